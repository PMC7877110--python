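"""Affinity propagation over edit-distance similarities, plus cluster analysis.

Affinity propagation (Frey & Dueck) exchanges two messages over the
similarity matrix S:

    responsibility  r(i,k) <- s(i,k) - max_{k' != k} { a(i,k') + s(i,k') }
    availability    a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))   (i != k)
                    a(k,k) <- sum_{i' != k} max(0, r(i',k))

with damping (new = damp * old + (1 - damp) * computed). Points k with
a(k,k) + r(k,k) > 0 are exemplars. The run counts as converged once the
exemplar set has been stable for ``conv_window`` consecutive sweeps; the
canonical final step then promotes, within each cluster, the member with
the largest within-cluster similarity sum to exemplar, and every point
takes the class of its most similar exemplar.

Out-of-sample (test) patterns inherit the class of the nearest exemplar
under the same window+complement edit distance used to build S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .pattern_extraction import LABEL_CLEAVAGE, Pattern
from .sequence_distance import SimilarityMatrix, batch_pattern_distances, pattern_distance


@dataclass
class ClusterModel:
    """Result of one affinity-propagation run."""

    exemplar_indices: np.ndarray  # sorted training-sample indices
    labels: np.ndarray  # per-sample class id (an exemplar index)
    converged: bool
    iterations_run: int
    R: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        ex = set(int(k) for k in self.exemplar_indices)
        for k in ex:
            if int(self.labels[k]) != k:
                raise ValueError(f"exemplar {k} does not label itself")
        for lab in self.labels:
            if int(lab) not in ex:
                raise ValueError(f"label {lab} is not an exemplar index")

    @property
    def n_clusters(self) -> int:
        return len(self.exemplar_indices)


def affinity_propagation(
    S: Union[SimilarityMatrix, np.ndarray],
    damping: float = 0.5,
    max_iter: int = 1000,
    conv_window: int = 50,
) -> ClusterModel:
    """Run affinity propagation until the exemplar set is stable or max_iter.

    Non-convergence is reported through ``converged=False``, not an error;
    callers following the repeated-split protocol discard such runs.
    """
    if not 0.5 <= damping < 1:
        raise ValueError("damping must be in [0.5, 1)")
    Sv = np.array(S.values if isinstance(S, SimilarityMatrix) else S, dtype=float)
    if np.isnan(Sv).any():
        raise ValueError("similarity matrix contains NaN")
    n = Sv.shape[0]
    idx = np.arange(n)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    e_hist = np.zeros((n, conv_window), dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities: subtract the best competing a + s (second-best for the argmax column)
        AS = A + Sv
        best_k = np.argmax(AS, axis=1)
        first = AS[idx, best_k].copy()
        AS[idx, best_k] = -np.inf
        second = AS.max(axis=1)
        Rnew = Sv - first[:, None]
        Rnew[idx, best_k] = Sv[idx, best_k] - second
        R = damping * R + (1 - damping) * Rnew

        # availabilities: column sums of positive responsibilities (self term kept as-is)
        Rp = np.maximum(R, 0)
        Rp[idx, idx] = R[idx, idx]
        colsum = Rp.sum(axis=0)
        Anew = colsum[None, :] - Rp
        diag = Anew[idx, idx].copy()  # sum_{i' != k} max(0, r(i',k))
        np.minimum(Anew, 0, out=Anew)
        Anew[idx, idx] = diag
        A = damping * A + (1 - damping) * Anew

        exemplar_mask = (np.diag(A) + np.diag(R)) > 0
        e_hist[:, (it - 1) % conv_window] = exemplar_mask
        if it >= conv_window:
            counts = e_hist.sum(axis=1)
            stable = np.all((counts == conv_window) | (counts == 0))
            if stable and exemplar_mask.any():
                converged = True
                break

    exemplars = np.flatnonzero((np.diag(A) + np.diag(R)) > 0)
    if exemplars.size == 0:
        # degenerate non-converged run: fall back to the single best candidate
        exemplars = np.array([int(np.argmax(np.diag(A) + np.diag(R)))])
        converged = False
    elif converged:
        # canonical final step (Frey & Dueck reference implementation): within
        # each message-passing cluster, promote the member maximising the
        # within-cluster similarity sum to exemplar
        c = np.argmax(Sv[:, exemplars], axis=1)
        c[exemplars] = np.arange(exemplars.size)
        for k in range(exemplars.size):
            members = np.flatnonzero(c == k)
            j = np.argmax(Sv[np.ix_(members, members)].sum(axis=0))
            exemplars[k] = members[j]
        exemplars = np.unique(exemplars)
    crit = Sv[:, exemplars]
    labels = exemplars[np.argmax(crit, axis=1)]  # argmax takes the lowest index on ties
    labels[exemplars] = exemplars
    return ClusterModel(
        exemplar_indices=exemplars,
        labels=labels,
        converged=converged,
        iterations_run=it,
        R=R,
        A=A,
    )


def assign_class(test: Pattern, exemplars: Sequence[Pattern], exemplar_ids: Sequence[int]) -> int:
    """Class of the exemplar with minimum window+complement edit distance.

    Ties go to the exemplar appearing first in ``exemplars`` (lowest index
    under the sorted exemplar order used throughout).
    """
    if len(exemplars) == 0:
        raise ValueError("no exemplars to assign against")
    best = min(range(len(exemplars)), key=lambda k: (pattern_distance(test, exemplars[k]), k))
    return int(exemplar_ids[best])


def assign_classes(
    tests: Sequence[Pattern], exemplars: Sequence[Pattern], exemplar_ids: Sequence[int]
) -> np.ndarray:
    """Vectorised nearest-exemplar assignment for a batch of test patterns."""
    if len(exemplars) == 0:
        raise ValueError("no exemplars to assign against")
    D = batch_pattern_distances(tests, exemplars)
    ids = np.asarray(exemplar_ids)
    return ids[np.argmin(D, axis=1)]


@dataclass(frozen=True)
class ClassRatio:
    """Cleavage fraction of one affinity-propagation class."""

    class_id: int
    n_cleavage: int
    n_noncleavage: int
    ratio: float
    bin_label: int


@dataclass(frozen=True)
class ClassRatioSummary:
    """Per-class cleavage ratios plus the per-bin aggregates."""

    per_class: tuple
    classes_per_bin: dict = field(default_factory=dict)
    samples_per_bin: dict = field(default_factory=dict)


def ratio_bin(ratio: float) -> int:
    """Label 1..5 for ratio in [0,0.2], (0.2,0.4], (0.4,0.6], (0.6,0.8], (0.8,1]."""
    if not 0 <= ratio <= 1:
        raise ValueError("ratio must be in [0, 1]")
    for b, hi in enumerate((0.2, 0.4, 0.6, 0.8), start=1):
        if ratio <= hi:
            return b
    return 5


def class_ratio_summary(
    cluster_labels: Sequence[int], pattern_labels: Sequence[str]
) -> ClassRatioSummary:
    """ratio_i(cleavage) = N_i(cleavage) / (N_i(cleavage) + N_i(non-cleavage)) per class."""
    cluster_labels = np.asarray(cluster_labels)
    is_cleavage = np.array([lab == LABEL_CLEAVAGE for lab in pattern_labels])
    if cluster_labels.shape[0] != is_cleavage.shape[0]:
        raise ValueError("cluster_labels and pattern_labels must align index-wise")
    per_class = []
    classes_per_bin = {b: 0 for b in range(1, 6)}
    samples_per_bin = {b: 0 for b in range(1, 6)}
    for cid in np.unique(cluster_labels):
        members = cluster_labels == cid
        n_pos = int(is_cleavage[members].sum())
        n_neg = int(members.sum()) - n_pos
        ratio = n_pos / (n_pos + n_neg)
        b = ratio_bin(ratio)
        per_class.append(ClassRatio(int(cid), n_pos, n_neg, ratio, b))
        classes_per_bin[b] += 1
        samples_per_bin[b] += n_pos + n_neg
    return ClassRatioSummary(tuple(per_class), classes_per_bin, samples_per_bin)
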