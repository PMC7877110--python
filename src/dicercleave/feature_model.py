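"""Relational/class feature encoding and the gradient-boosted classifier.

Each window position i contributes one categorical *relational feature*
p_i = (window[i], complement[i]) drawn from {A,C,G,U} x {A,C,G,U,O} — 20
possible pair codes. The affinity-propagation class id is a 15th
categorical feature. LightGBM consumes the categorical columns natively
(no one-hot encoding); hyperparameters are chosen by exhaustive grid search
with stratified cross-validated accuracy on the training set only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from lightgbm import Booster, LGBMClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .pattern_extraction import LABEL_CLEAVAGE, Pattern

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGU"
PARTNERS = "ACGUO"
#: the 20 ordered (nucleotide, partner) pair codes, e.g. "UA", "UO"
PAIR_CATEGORIES = tuple(n + p for n in NUCLEOTIDES for p in PARTNERS)
#: reserved code for a category unseen at training time
UNSEEN = "unseen"

RELATIONAL_COLUMNS = tuple(f"p{i}" for i in range(1, 15))
CLASS_COLUMN = "class_feature"
FEATURE_COLUMNS = RELATIONAL_COLUMNS + (CLASS_COLUMN,)
LABEL_COLUMN = "label"

#: hyperparameter search grid (6 x 3 x 3)
DEFAULT_GRID: dict = {
    "max_depth": [10, 20, 30, 40, 50, 60],
    "learning_rate": [0.05, 0.1, 0.15],
    "num_leaves": [200, 300, 400],
}


def relational_encode(pattern: Pattern) -> list[str]:
    """The 14 pair codes p1..p14 = (window[i], complement[i])."""
    return [w + c for w, c in zip(pattern.window, pattern.complement)]


def relational_decode(codes: Sequence[str]) -> tuple[str, str]:
    """Inverse of :func:`relational_encode`: recover (window, complement)."""
    return "".join(c[0] for c in codes), "".join(c[1] for c in codes)


def build_feature_table(
    patterns: Sequence[Pattern],
    class_ids: Sequence[int],
    class_categories: Sequence | None = None,
) -> pd.DataFrame:
    """Assemble the 15-categorical-feature table plus the binary label.

    ``class_categories`` fixes the class-feature dictionary (pass the
    training table's categories when encoding a test set so codes are
    shared); a class id outside the dictionary maps to the reserved
    ``unseen`` code with a warning. The relational dictionary is the full
    20-code alphabet and is identical for every table.
    """
    if len(patterns) != len(class_ids):
        raise ValueError("patterns and class_ids must align")
    rows = [relational_encode(p) for p in patterns]
    df = pd.DataFrame(rows, columns=list(RELATIONAL_COLUMNS))
    pair_dtype = pd.CategoricalDtype(list(PAIR_CATEGORIES) + [UNSEEN])
    for col in RELATIONAL_COLUMNS:
        df[col] = df[col].astype(pair_dtype)
        if df[col].isna().any():  # cannot happen for valid patterns, but stay safe
            logger.warning("column %s: unknown pair code mapped to %r", col, UNSEEN)
            df[col] = df[col].fillna(UNSEEN)

    if class_categories is None:
        class_categories = sorted(set(int(c) for c in class_ids))
    class_dtype = pd.CategoricalDtype(list(class_categories) + [UNSEEN])
    cls = pd.Series([int(c) for c in class_ids]).astype(class_dtype)
    if cls.isna().any():
        logger.warning(
            "%d class ids unseen at training time mapped to %r", int(cls.isna().sum()), UNSEEN
        )
        cls = cls.fillna(UNSEEN)
    df[CLASS_COLUMN] = cls
    df[LABEL_COLUMN] = [int(p.label == LABEL_CLEAVAGE) for p in patterns]
    return df


@dataclass
class TrainedModel:
    """A fitted boosted-tree ensemble plus the dictionaries needed to reuse it."""

    estimator: LGBMClassifier | None
    best_params: dict
    class_categories: list
    cv_results: dict | None = None
    booster: Booster | None = None

    def _booster(self) -> Booster:
        return self.estimator.booster_ if self.estimator is not None else self.booster

    def importance(self, importance_type: str = "split") -> np.ndarray:
        """Per-feature importance (length 15), split counts or total gain."""
        return self._booster().feature_importance(importance_type=importance_type)

    def save(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self._booster().save_model(str(directory / "model.txt"))
        sidecar = {
            "best_params": self.best_params,
            "class_categories": [int(c) for c in self.class_categories],
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "TrainedModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        booster = Booster(model_file=str(directory / "model.txt"))
        return cls(
            estimator=None,
            best_params=sidecar["best_params"],
            class_categories=sidecar["class_categories"],
            booster=booster,
        )


def _make_estimator(seed: int, n_estimators: int, **params) -> LGBMClassifier:
    return LGBMClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
        **params,
    )


def grid_search_train(
    train_table: pd.DataFrame,
    grid: Mapping[str, Sequence] = DEFAULT_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
) -> TrainedModel:
    """Exhaustive grid search by stratified k-fold CV accuracy, then refit.

    The winning combination (ties broken by grid order) is refit on the full
    training table. Categorical features are passed to LightGBM natively via
    pandas ``category`` dtype.
    """
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    X = train_table[list(FEATURE_COLUMNS)]
    y = train_table[LABEL_COLUMN]
    if y.nunique() < 2:
        raise ValueError("training labels are single-class")
    search = GridSearchCV(
        _make_estimator(seed, n_estimators),
        param_grid=dict(grid),
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    return TrainedModel(
        estimator=search.best_estimator_,
        best_params=dict(search.best_params_),
        class_categories=[c for c in X[CLASS_COLUMN].cat.categories if c != UNSEEN],
        cv_results={
            "params": list(search.cv_results_["params"]),
            "mean_test_score": search.cv_results_["mean_test_score"].tolist(),
        },
    )


def predict(model: TrainedModel, test_table: pd.DataFrame) -> pd.DataFrame:
    """Per-row cleavage probability and the 0.5-threshold binary call."""
    missing = [c for c in FEATURE_COLUMNS if c not in test_table.columns]
    if missing:
        raise ValueError(f"test table is missing feature columns: {missing}")
    X = test_table[list(FEATURE_COLUMNS)]
    bad = [c for c in FEATURE_COLUMNS if not isinstance(X[c].dtype, pd.CategoricalDtype)]
    if bad:
        raise ValueError(f"feature columns are not categorical: {bad}")
    if model.estimator is not None:
        proba = model.estimator.predict_proba(X)[:, 1]
    else:
        proba = model.booster.predict(X)
    return pd.DataFrame(
        {"probability": proba, "prediction": (proba > 0.5).astype(int)},
        index=test_table.index,
    )


def feature_importance_report(
    models: Union[TrainedModel, Iterable[TrainedModel]],
) -> pd.DataFrame:
    """Mean split-count and gain importance per feature, ranked by split count.

    Accepts one model or an iterable (the repeated-split protocol averages
    importances over the trained models).
    """
    if isinstance(models, TrainedModel):
        models = [models]
    models = list(models)
    split = np.mean([m.importance("split") for m in models], axis=0)
    gain = np.mean([m.importance("gain") for m in models], axis=0)
    df = pd.DataFrame(
        {"feature": list(FEATURE_COLUMNS), "split_importance": split, "gain_importance": gain}
    )
    return df.sort_values("split_importance", ascending=False, ignore_index=True)
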