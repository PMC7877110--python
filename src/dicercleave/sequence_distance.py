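"""Edit distance, pattern similarity, and the similarity matrix for clustering.

The similarity between two patterns E and F is

    D_similar(E, F) = D_edit(E.window, F.window) + D_edit(E.complement, F.complement)

with D_edit the classic Levenshtein distance (unit insert/delete/substitute
costs; the loop/bulge symbol 'O' is an ordinary character). Affinity
propagation consumes the n x n similarity matrix S with off-diagonal entries
s(i, j) = -D_similar(i, j) and the diagonal set to the clustering
*preference* (default: median of the off-diagonal similarities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .pattern_extraction import Pattern

# alphabet for integer-coding pattern strings; 'O' is the loop/bulge symbol
_ALPHABET = "ACGUO"
_CODE = {c: k for k, c in enumerate(_ALPHABET)}


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance via the standard DP recursion, two-row memory."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[len(b)]


def pattern_distance(e: Pattern, f: Pattern) -> int:
    """D_similar: window edit distance plus complement edit distance."""
    return edit_distance(e.window, f.window) + edit_distance(e.complement, f.complement)


def _encode(strings: Sequence[str]) -> np.ndarray:
    arr = np.empty((len(strings), len(strings[0])), dtype=np.int8)
    for r, s in enumerate(strings):
        arr[r] = [_CODE[c] for c in s]
    return arr


def batch_edit_distances(xs: Sequence[str], ys: Sequence[str] | None = None) -> np.ndarray:
    """All-pairs Levenshtein distances between two lists of equal-length strings.

    Vectorises the DP over the pair grid: for m-length strings the loop runs
    (m+1)^2 steps, each an O(|xs|*|ys|) numpy operation. Returns an
    ``len(xs) x len(ys)`` integer matrix (ys defaults to xs).
    """
    X = _encode(xs)
    Y = X if ys is None else _encode(ys)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("batch mode requires equal-length strings")
    m = X.shape[1]
    nx, ny = X.shape[0], Y.shape[0]
    prev = np.empty((m + 1, nx, ny), dtype=np.int32)
    cur = np.empty_like(prev)
    prev[:] = np.arange(m + 1)[:, None, None]  # row i=0: D(0, j) = j
    for i in range(1, m + 1):
        cur[0] = i
        xi = X[:, i - 1][:, None]  # broadcast over ys
        for j in range(1, m + 1):
            sub = prev[j - 1] + (xi != Y[:, j - 1][None, :])
            np.minimum(prev[j] + 1, cur[j - 1] + 1, out=cur[j])
            np.minimum(cur[j], sub, out=cur[j])
        prev, cur = cur, prev
    return prev[m].copy()


def batch_pattern_distances(
    patterns: Sequence[Pattern], others: Sequence[Pattern] | None = None
) -> np.ndarray:
    """D_similar for every pair; vectorised counterpart of :func:`pattern_distance`."""
    w = batch_edit_distances(
        [p.window for p in patterns], None if others is None else [p.window for p in others]
    )
    c = batch_edit_distances(
        [p.complement for p in patterns],
        None if others is None else [p.complement for p in others],
    )
    return w + c


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric n x n similarity matrix with non-positive off-diagonal entries."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and off.max() > 0:
            raise ValueError("off-diagonal similarities must be <= 0")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_similarity_matrix(
    patterns: Sequence[Pattern],
    preference: Union[str, float] = "median",
) -> SimilarityMatrix:
    """S with s(i,j) = -D_similar(i,j) off-diagonal and the preference on the diagonal.

    ``preference`` is either a number or ``"median"`` / ``"min"`` of the
    off-diagonal similarities (median is standard affinity-propagation
    practice and the default).
    """
    n = len(patterns)
    if n < 2:
        raise ValueError(f"need at least 2 patterns, got {n}")
    S = -batch_pattern_distances(patterns).astype(float)
    off = S[~np.eye(n, dtype=bool)]
    if preference == "median":
        pref = float(np.median(off))
    elif preference == "min":
        pref = float(off.min())
    else:
        pref = float(preference)
    np.fill_diagonal(S, pref)
    return SimilarityMatrix(S)
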