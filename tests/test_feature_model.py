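"""Relational encoding, feature tables, grid search, prediction, importance."""

import logging

import numpy as np
import pandas as pd
import pytest
from lightgbm import LGBMClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from dicercleave import (
    LABEL_CLEAVAGE,
    LABEL_NONCLEAVAGE,
    Pattern,
    TrainedModel,
    build_feature_table,
    extract_cleavage_pattern,
    feature_importance_report,
    grid_search_train,
    predict,
    relational_encode,
)
from dicercleave.feature_model import (
    FEATURE_COLUMNS,
    PAIR_CATEGORIES,
    UNSEEN,
    relational_decode,
)

TINY_GRID = {"max_depth": [10], "learning_rate": [0.1], "num_leaves": [31]}


def random_patterns(n, rng, positional_signal=False):
    """Balanced patterns; with positional_signal, window position 8 encodes the label."""
    pats = []
    for k in range(n):
        label = LABEL_CLEAVAGE if k % 2 == 0 else LABEL_NONCLEAVAGE
        window = list(rng.choice(list("ACGU"), 14))
        if positional_signal:
            window[7] = "G" if label == LABEL_CLEAVAGE else "A"
        complement = "".join(rng.choice(list("ACGUO"), 14))
        pats.append(Pattern(f"m{k}", "5p", label, "".join(window), complement, 0))
    return pats


class TestRelationalEncoding:
    def test_worked_example_pairs(self, fig2):
        pre, table, ann = fig2
        pairs = relational_encode(extract_cleavage_pattern(pre, table, ann))
        assert pairs == [
            "UA", "AU", "UA", "AU", "GC", "UA", "UA",
            "UO", "UO", "AO", "GC", "GC", "GC", "UO",
        ]

    def test_fully_unpaired_all_o_partners(self):
        p = Pattern("x", "5p", LABEL_CLEAVAGE, "ACGUACGUACGUAC", "O" * 14, 0)
        assert all(code[1] == "O" for code in relational_encode(p))

    def test_encoding_is_a_bijection(self, noisy_patterns_5p):
        for p in noisy_patterns_5p[:20]:
            assert relational_decode(relational_encode(p)) == (p.window, p.complement)

    def test_twenty_pair_alphabet(self):
        assert len(PAIR_CATEGORIES) == 20
        assert len(set(PAIR_CATEGORIES)) == 20


class TestFeatureTable:
    def test_shape_and_dtypes(self, noisy_patterns_5p):
        pats = noisy_patterns_5p[:10]
        df = build_feature_table(pats, [0] * 10)
        assert df.shape == (10, 16)
        for col in FEATURE_COLUMNS:
            assert isinstance(df[col].dtype, pd.CategoricalDtype)
        assert set(df["label"]) == {0, 1}

    def test_unseen_class_id_mapped_to_reserved_code(self, noisy_patterns_5p, caplog):
        pats = noisy_patterns_5p[:4]
        with caplog.at_level(logging.WARNING):
            df = build_feature_table(pats, [0, 0, 1, 99], class_categories=[0, 1])
        assert df["class_feature"].tolist() == [0, 0, 1, UNSEEN]
        assert "unseen" in caplog.text

    def test_train_and_test_share_pair_dictionary(self, noisy_patterns_5p):
        a = build_feature_table(noisy_patterns_5p[:5], [0] * 5)
        b = build_feature_table(noisy_patterns_5p[5:10], [0] * 5)
        for col in FEATURE_COLUMNS[:-1]:
            assert (a[col].cat.categories == b[col].cat.categories).all()


class TestGridSearchTrain:
    def test_single_point_grid_equivalent_to_direct_training(self):
        rng = np.random.default_rng(0)
        pats = random_patterns(60, rng, positional_signal=True)
        table = build_feature_table(pats, [0] * 60)
        model = grid_search_train(table, grid=TINY_GRID, cv_folds=3, seed=1)
        direct = LGBMClassifier(
            n_estimators=100, random_state=1, n_jobs=1, verbose=-1,
            max_depth=10, learning_rate=0.1, num_leaves=31,
        ).fit(table[list(FEATURE_COLUMNS)], table["label"])
        X = table[list(FEATURE_COLUMNS)]
        assert (model.estimator.predict(X) == direct.predict(X)).all()

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(1)
        pats = random_patterns(60, rng, positional_signal=True)
        table = build_feature_table(pats, [0] * 60)
        grid = {"max_depth": [5, 10], "learning_rate": [0.1], "num_leaves": [15, 31]}
        m1 = grid_search_train(table, grid=grid, cv_folds=3, seed=7)
        m2 = grid_search_train(table, grid=grid, cv_folds=3, seed=7)
        assert m1.best_params == m2.best_params
        assert (m1.importance("split") == m2.importance("split")).all()

    def test_selection_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        pats = random_patterns(80, rng, positional_signal=True)
        table = build_feature_table(pats, [0] * 80)
        grid = {"max_depth": [2, 10], "learning_rate": [0.01, 0.1], "num_leaves": [4, 31]}
        model = grid_search_train(table, grid=grid, cv_folds=3, seed=5)
        X, y = table[list(FEATURE_COLUMNS)], table["label"]
        cv = StratifiedKFold(3, shuffle=True, random_state=5)
        best_score = np.mean(
            cross_val_score(
                LGBMClassifier(n_estimators=100, random_state=5, n_jobs=1, verbose=-1,
                               **model.best_params),
                X, y, cv=cv, scoring="accuracy",
            )
        )
        for md in grid["max_depth"]:
            for lr in grid["learning_rate"]:
                for nl in grid["num_leaves"]:
                    score = np.mean(
                        cross_val_score(
                            LGBMClassifier(n_estimators=100, random_state=5, n_jobs=1,
                                           verbose=-1, max_depth=md, learning_rate=lr,
                                           num_leaves=nl),
                            X, y, cv=cv, scoring="accuracy",
                        )
                    )
                    assert best_score >= score - 1e-12

    def test_empty_grid_rejected(self, noisy_patterns_5p):
        table = build_feature_table(noisy_patterns_5p[:10], [0] * 10)
        with pytest.raises(ValueError):
            grid_search_train(table, grid={})


class TestPredict:
    def test_overfit_model_memorises_training_rows(self):
        rng = np.random.default_rng(3)
        pats = random_patterns(40, rng, positional_signal=True)
        table = build_feature_table(pats, [0] * 40)
        grid = {
            "min_child_samples": [1], "min_data_per_group": [1],
            "cat_smooth": [0.1], "cat_l2": [0.1], "num_leaves": [31],
        }
        model = grid_search_train(table, grid=grid, cv_folds=2, seed=0)
        pred = predict(model, table)
        correct_class_prob = np.where(table["label"] == 1, pred["probability"],
                                      1 - pred["probability"])
        assert (correct_class_prob > 0.5).all()

    def test_identical_rows_identical_probabilities(self):
        rng = np.random.default_rng(4)
        pats = random_patterns(40, rng, positional_signal=True)
        table = build_feature_table(pats, [0] * 40)
        model = grid_search_train(table, grid=TINY_GRID, cv_folds=2, seed=0)
        dup = pd.concat([table.iloc[[0]]] * 5, ignore_index=True)
        pred = predict(model, dup)
        assert pred["probability"].nunique() == 1

    def test_schema_mismatch_lists_offending_columns(self):
        rng = np.random.default_rng(5)
        pats = random_patterns(20, rng)
        table = build_feature_table(pats, [0] * 20)
        model = grid_search_train(table, grid=TINY_GRID, cv_folds=2, seed=0)
        with pytest.raises(ValueError, match="p14"):
            predict(model, table.drop(columns=["p14"]))

    def test_serialization_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(6)
        pats = random_patterns(40, rng, positional_signal=True)
        table = build_feature_table(pats, [0] * 40)
        model = grid_search_train(table, grid=TINY_GRID, cv_folds=2, seed=0)
        model.save(tmp_path / "model")
        loaded = TrainedModel.load(tmp_path / "model")
        p1 = predict(model, table)["probability"]
        p2 = predict(loaded, table)["probability"]
        assert np.allclose(p1, p2)
        assert loaded.best_params == model.best_params


class TestFeatureImportance:
    def test_planted_signal_position_ranks_first(self):
        rng = np.random.default_rng(7)
        pats = random_patterns(300, rng, positional_signal=True)
        table = build_feature_table(pats, [0] * 300)
        model = grid_search_train(table, grid=TINY_GRID, cv_folds=2, seed=0)
        report = feature_importance_report(model)
        assert report.iloc[0]["feature"] == "p8"

    def test_constant_features_give_zero_importances(self):
        pats = [
            Pattern(f"c{k}", "5p", LABEL_CLEAVAGE if k % 2 == 0 else LABEL_NONCLEAVAGE,
                    "A" * 14, "U" * 14, 0)
            for k in range(20)
        ]
        table = build_feature_table(pats, [0] * 20)
        model = grid_search_train(table, grid=TINY_GRID, cv_folds=2, seed=0)
        assert (model.importance("split") == 0).all()

    def test_averaging_identical_models_is_identity(self):
        rng = np.random.default_rng(8)
        pats = random_patterns(40, rng, positional_signal=True)
        table = build_feature_table(pats, [0] * 40)
        model = grid_search_train(table, grid=TINY_GRID, cv_folds=2, seed=0)
        single = feature_importance_report(model)
        doubled = feature_importance_report([model, model])
        pd.testing.assert_frame_equal(single, doubled)

    def test_importance_vector_has_fifteen_entries(self):
        rng = np.random.default_rng(9)
        pats = random_patterns(40, rng, positional_signal=True)
        table = build_feature_table(pats, [0] * 40)
        model = grid_search_train(table, grid=TINY_GRID, cv_folds=2, seed=0)
        assert model.importance("split").shape == (15,)
        assert (model.importance("gain") >= 0).all()
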