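"""Classification metrics and the repeated random-split evaluation protocol.

Each repeat draws a disjoint stratified train/test split *over pre-miRNA
ids* (so a cleavage pattern and its sibling non-cleavage pattern never
straddle the split), clusters the training patterns with affinity
propagation, assigns test patterns to the nearest exemplar, grid-searches
and fits the boosted-tree classifier, and scores the held-out patterns.
Repeats whose affinity propagation fails to converge are discarded and
re-drawn, mirroring the protocol of keeping only converged runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence, Union

import numpy as np

from .clustering import affinity_propagation, assign_classes
from .feature_model import (
    CLASS_COLUMN,
    DEFAULT_GRID,
    UNSEEN,
    build_feature_table,
    grid_search_train,
    predict,
)
from .pattern_extraction import LABEL_CLEAVAGE, LABEL_NONCLEAVAGE, Pattern
from .sequence_distance import build_similarity_matrix


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(((yt == 1) & (yp == 1)).sum()),
            TN=int(((yt == 0) & (yp == 0)).sum()),
            FP=int(((yt == 0) & (yp == 1)).sum()),
            FN=int(((yt == 1) & (yp == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy, and Matthews correlation coefficient."""

    Sn: float
    Sp: float
    Acc: float
    MCC: float
    mcc_undefined: bool = False

    def as_dict(self) -> dict:
        return {"Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc, "MCC": self.MCC}


def compute_metrics(cc: ConfusionCounts) -> MetricSet:
    """Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc, and the MCC closed form.

    A zero MCC denominator (a degenerate margin) is reported as MCC = 0
    with the ``mcc_undefined`` flag set.
    """
    if cc.total == 0:
        raise ValueError("empty confusion table")
    sn = cc.TP / (cc.TP + cc.FN) if cc.TP + cc.FN else 0.0
    sp = cc.TN / (cc.TN + cc.FP) if cc.TN + cc.FP else 0.0
    acc = (cc.TP + cc.TN) / cc.total
    denom = (
        (cc.TP + cc.FP) * (cc.TP + cc.FN) * (cc.TN + cc.FP) * (cc.TN + cc.FN)
    )
    if denom == 0:
        return MetricSet(sn, sp, acc, 0.0, mcc_undefined=True)
    mcc = (cc.TP * cc.TN - cc.FP * cc.FN) / math.sqrt(denom)
    return MetricSet(sn, sp, acc, mcc)


@dataclass
class RepeatResult:
    """One retained (converged) repeat of the experiment."""

    repeat_index: int
    redraws: int
    metrics: MetricSet
    best_params: dict
    n_clusters: int
    ap_iterations: int
    train_ids: tuple
    test_ids: tuple
    importance_split: np.ndarray
    importance_gain: np.ndarray


@dataclass
class ExperimentReport:
    repeats: list
    mean: MetricSet
    master_seed: int

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "mean": self.mean.as_dict(),
            "repeats": [
                {
                    "repeat_index": r.repeat_index,
                    "redraws": r.redraws,
                    "metrics": r.metrics.as_dict(),
                    "best_params": r.best_params,
                    "n_clusters": r.n_clusters,
                    "ap_iterations": r.ap_iterations,
                }
                for r in self.repeats
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _group_by_id(patterns: Sequence[Pattern]) -> dict:
    """Map id -> (cleavage pattern, non-cleavage pattern); drop incomplete ids."""
    groups: dict[str, dict[str, Pattern]] = {}
    for p in patterns:
        groups.setdefault(p.premirna_id, {})[p.label] = p
    return {
        rid: (g[LABEL_CLEAVAGE], g[LABEL_NONCLEAVAGE])
        for rid, g in groups.items()
        if LABEL_CLEAVAGE in g and LABEL_NONCLEAVAGE in g
    }


def run_experiment(
    patterns: Sequence[Pattern],
    n_repeats: int = 10,
    train_pos: int = 800,
    train_neg: int = 800,
    test_pos: int = 156,
    test_neg: int = 156,
    seed: int = 0,
    grid: Mapping = DEFAULT_GRID,
    cv_folds: int = 5,
    damping: float = 0.5,
    max_iter: int = 1000,
    conv_window: int = 50,
    preference: Union[str, float] = "median",
    n_estimators: int = 100,
    shuffle_labels: bool = False,
    max_redraws: int = 5,
) -> ExperimentReport:
    """The repeated-split protocol: split, cluster, assign, train, score.

    Splits are drawn over pre-miRNA ids, so ``train_pos == train_neg`` and
    ``test_pos == test_neg`` are required (each id contributes one pattern
    of each class). ``shuffle_labels=True`` runs the permutation null: the
    two labels of each id are swapped with probability 1/2, destroying the
    label/window association while preserving class balance. Everything is
    deterministic given ``seed``; per-repeat generators are derived from
    (seed, repeat, redraw).
    """
    if train_pos != train_neg or test_pos != test_neg:
        raise ValueError("id-level splitting requires train_pos==train_neg and test_pos==test_neg")
    groups = _group_by_id(patterns)
    ids = sorted(groups)
    need = train_pos + test_pos
    if len(ids) < need:
        raise ValueError(
            f"insufficient pre-miRNA ids: need {need} ({train_pos} train + {test_pos} test), "
            f"have {len(ids)}"
        )

    repeats: list[RepeatResult] = []
    for r in range(n_repeats):
        result = None
        for redraw in range(max_redraws + 1):
            rng = np.random.default_rng((seed, r, redraw))
            perm = rng.permutation(ids)
            train_ids = list(perm[:train_pos])
            test_ids = list(perm[train_pos : train_pos + test_pos])
            assert not set(train_ids) & set(test_ids), "train/test id leakage"

            def collect(id_list):
                pats = []
                for rid in id_list:
                    pos, neg = groups[rid]
                    if shuffle_labels and rng.random() < 0.5:
                        pos = replace(pos, label=LABEL_NONCLEAVAGE)
                        neg = replace(neg, label=LABEL_CLEAVAGE)
                    pats.extend((pos, neg))
                return pats

            train_patterns = collect(train_ids)
            test_patterns = collect(test_ids)

            S = build_similarity_matrix(train_patterns, preference)
            cm = affinity_propagation(S, damping=damping, max_iter=max_iter, conv_window=conv_window)
            if not cm.converged:
                continue

            exemplar_patterns = [train_patterns[int(k)] for k in cm.exemplar_indices]
            test_classes = assign_classes(test_patterns, exemplar_patterns, cm.exemplar_indices)
            train_table = build_feature_table(train_patterns, cm.labels)
            class_cats = [c for c in train_table[CLASS_COLUMN].cat.categories if c != UNSEEN]
            test_table = build_feature_table(test_patterns, test_classes, class_cats)

            fit_seed = int(rng.integers(2**31 - 1))
            model = grid_search_train(
                train_table, grid=grid, cv_folds=cv_folds, seed=fit_seed, n_estimators=n_estimators
            )
            pred = predict(model, test_table)
            cc = ConfusionCounts.from_predictions(test_table["label"], pred["prediction"])
            result = RepeatResult(
                repeat_index=r,
                redraws=redraw,
                metrics=compute_metrics(cc),
                best_params=model.best_params,
                n_clusters=cm.n_clusters,
                ap_iterations=cm.iterations_run,
                train_ids=tuple(train_ids),
                test_ids=tuple(test_ids),
                importance_split=model.importance("split"),
                importance_gain=model.importance("gain"),
            )
            break
        if result is None:
            raise RuntimeError(
                f"repeat {r}: affinity propagation failed to converge in "
                f"{max_redraws + 1} split draws"
            )
        repeats.append(result)

    mean = MetricSet(
        Sn=float(np.mean([r.metrics.Sn for r in repeats])),
        Sp=float(np.mean([r.metrics.Sp for r in repeats])),
        Acc=float(np.mean([r.metrics.Acc for r in repeats])),
        MCC=float(np.mean([r.metrics.MCC for r in repeats])),
        mcc_undefined=any(r.metrics.mcc_undefined for r in repeats),
    )
    return ExperimentReport(repeats=repeats, mean=mean, master_seed=seed)
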