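"""Splitting, classification, regression, grid search, feature comparison."""

import numpy as np
import pandas as pd
import pytest

import sensorscape as ss
from sensorscape.models import (
    EvalReport,
    ModelConfig,
    SensorProfileClassifier,
    SensorProfileRegressor,
    SplitSpec,
    evaluate,
    evaluate_r2,
    feature_set_comparison,
    grid_search,
    split,
    train_classifier,
    train_regressor,
)
from sensorscape.profile import SensorProfileMatrix

SMALL_GRID = {"learning_rate": [0.1], "depth": [4], "l2_leaf_reg": [3.0]}


def _labels(n_per_class, classes=("a", "b")):
    lab = []
    for c in classes:
        lab += [c] * n_per_class
    return pd.Series(lab, index=[f"M{i}" for i in range(len(lab))])


class TestSplit:
    def test_sizes_70_20_10(self):
        tr, te, va = split(_labels(50), SplitSpec(seed=1))
        assert (len(tr), len(te), len(va)) == (70, 20, 10)
        assert set(tr) | set(te) | set(va) == set(_labels(50).index)
        assert not (set(tr) & set(te)) and not (set(te) & set(va))

    def test_deterministic(self):
        a = split(_labels(50), SplitSpec(seed=3))
        b = split(_labels(50), SplitSpec(seed=3))
        assert a == b

    def test_stratified_proportions_within_one(self):
        labels = _labels(50)
        tr, te, va = split(labels, SplitSpec(seed=0))
        for part, frac in ((tr, 0.7), (te, 0.2), (va, 0.1)):
            counts = labels.loc[part].value_counts()
            for c in ("a", "b"):
                assert abs(counts[c] - frac * 50) <= 1

    def test_small_class_error_names_class(self):
        labels = pd.Series(["a"] * 10 + ["tiny"] * 2, index=[f"M{i}" for i in range(12)])
        with pytest.raises(ValueError, match="tiny"):
            split(labels, SplitSpec())

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.5, 0.2))


class TestClassifier:
    def test_separable_two_class_perfect(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f0": np.r_[rng.uniform(0, 0.2, 40), rng.uniform(0.8, 1.0, 40)],
                          "f1": rng.uniform(size=80)})
        y = pd.Series(["lo"] * 40 + ["hi"] * 40, index=X.index)
        cfg = ModelConfig(grid=SMALL_GRID, n_estimators=60)
        model = train_classifier(X.iloc[:60], y.iloc[:60], cfg)
        assert (model.predict(X.iloc[60:]) == y.iloc[60:]).all()

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.rand(10, 2))
        with pytest.raises(ValueError, match="single class"):
            SensorProfileClassifier().fit(X, np.zeros(10))

    def test_sklearn_params_roundtrip(self):
        est = SensorProfileClassifier(depth=3)
        assert est.get_params()["depth"] == 3
        est.set_params(depth=5)
        assert est.depth == 5

    def test_disjoint_support_ecosystems_recovered(self, disjoint_matrix):
        labels = disjoint_matrix.meta["ecosystem"]
        tr, te, va = split(labels, SplitSpec(seed=0))
        cfg = ModelConfig(grid=SMALL_GRID, n_estimators=100)
        model = train_classifier(disjoint_matrix.values.loc[tr], labels.loc[tr], cfg)
        rep = evaluate(model, disjoint_matrix.values.loc[te], labels.loc[te])
        assert rep.accuracy >= 0.95

    def test_label_permutation_is_chance(self, disjoint_matrix):
        rng = np.random.default_rng(1)
        labels = disjoint_matrix.meta["ecosystem"].copy()
        labels[:] = rng.permutation(labels.to_numpy())
        tr, te, va = split(labels, SplitSpec(seed=0))
        cfg = ModelConfig(grid=SMALL_GRID, n_estimators=100)
        model = train_classifier(disjoint_matrix.values.loc[tr], labels.loc[tr], cfg)
        rep = evaluate(model, disjoint_matrix.values.loc[te], labels.loc[te])
        p = 0.25
        half_width = 1.96 * np.sqrt(p * (1 - p) / len(te))
        assert abs(rep.accuracy - p) <= half_width


class TestEvaluate:
    def test_hand_confusion_matrix(self):
        class Stub:
            classes_ = np.array(["a", "b", "c"])

            def predict(self, X):
                return np.array(["a", "b", "b", "c", "a", "a"])

        y = pd.Series(["a", "b", "c", "c", "a", "b"])
        rep = evaluate(Stub(), pd.DataFrame(np.zeros((6, 1))), y)
        assert rep.accuracy == pytest.approx(4 / 6)
        assert rep.confusion.loc["a", "a"] == 2
        assert rep.confusion.loc["b", "b"] == 1
        assert rep.confusion.loc["b", "a"] == 1
        assert rep.confusion.loc["c", "c"] == 1
        assert rep.confusion.loc["c", "b"] == 1
        # row sums equal per-class test counts; trace/total equals accuracy
        assert rep.confusion.sum(axis=1).to_dict() == {"a": 2, "b": 2, "c": 2}
        assert np.trace(rep.confusion.to_numpy()) / 6 == pytest.approx(rep.accuracy)

    def test_unseen_label_flagged(self):
        class Stub:
            classes_ = np.array(["a", "b"])

            def predict(self, X):
                return np.array(["a", "a"])

        rep = evaluate(Stub(), pd.DataFrame(np.zeros((2, 1))), pd.Series(["a", "zzz"]))
        assert rep.unseen_labels == ["zzz"]
        assert rep.confusion.loc["zzz"].sum() == 1

    def test_empty_test_set_rejected(self):
        class Stub:
            classes_ = np.array(["a", "b"])

        with pytest.raises(ValueError, match="empty"):
            evaluate(Stub(), pd.DataFrame(), pd.Series(dtype=object))


class TestGridSearch:
    def test_single_point_grid_returns_it(self):
        X = pd.DataFrame(np.random.default_rng(0).random((40, 3)))
        y = pd.Series(["a", "b"] * 20)
        cfg = ModelConfig(grid=SMALL_GRID, n_estimators=20)
        best, model = grid_search(X[:30], y[:30], X[30:], y[30:], cfg)
        assert best == {"learning_rate": 0.1, "depth": 4, "l2_leaf_reg": 3.0}

    def test_picks_good_over_crippled(self):
        # XOR labels: depth-1 stumps cannot express the interaction, deeper trees can
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.uniform(size=(160, 2)), columns=["f0", "f1"])
        y = pd.Series(
            np.where((X["f0"] > 0.5) ^ (X["f1"] > 0.5), "odd", "even"), index=X.index
        )
        tr, te, va = split(y, SplitSpec(seed=0))
        cfg = ModelConfig(
            grid={"learning_rate": [0.1], "depth": [1, 4], "l2_leaf_reg": [3.0]},
            n_estimators=60,
        )
        best, model = grid_search(X.loc[tr], y.loc[tr], X.loc[va], y.loc[va], cfg)
        assert best["depth"] == 4

    def test_ties_prefer_first_grid_point(self):
        X = pd.DataFrame({"f0": [0.0] * 20})  # no signal: every point ties
        y = pd.Series(["a", "b"] * 10)
        cfg = ModelConfig(
            grid={"learning_rate": [0.3, 0.1], "depth": [2, 3], "l2_leaf_reg": [1.0]},
            n_estimators=10,
        )
        best, _ = grid_search(X[:14], y[:14], X[14:], y[14:], cfg)
        assert best == {"learning_rate": 0.3, "depth": 2, "l2_leaf_reg": 1.0}


class TestRegressor:
    def _planted(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.random((n, 6)), columns=[f"C{i}" for i in range(6)])
        y = 3.0 * X["C1"] - 2.0 * X["C4"]
        return X, y

    def test_linear_signal_recovered(self):
        X, y = self._planted()
        cfg = ModelConfig(task="regression", grid=SMALL_GRID, n_estimators=200)
        model = train_regressor(X[:150], y[:150], cfg)
        assert evaluate_r2(model, X[150:], y[150:]) >= 0.95

    def test_independent_target_has_no_skill(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((200, 5)))
        y = pd.Series(rng.normal(size=200))
        cfg = ModelConfig(task="regression", grid=SMALL_GRID, n_estimators=60)
        model = train_regressor(X[:150], y[:150], cfg)
        assert evaluate_r2(model, X[150:], y[150:]) <= 0.1

    def test_mean_prediction_r2_zero(self):
        y_true = np.array([1.0, 2.0, 3.0, 4.0])

        class Mean:
            def predict(self, X):
                return np.full(len(X), y_true.mean())

        assert evaluate_r2(Mean(), pd.DataFrame(np.zeros((4, 1))), y_true) == pytest.approx(0.0)

    def test_constant_target_rejected(self):
        X = pd.DataFrame(np.random.rand(10, 2))
        with pytest.raises(ValueError, match="constant"):
            SensorProfileRegressor().fit(X, np.ones(10))


class TestFeatureSetComparison:
    def test_identical_matrices_identical_accuracy(self, disjoint_matrix):
        cfg = ModelConfig(grid=SMALL_GRID, n_estimators=60)
        copy = SensorProfileMatrix(
            disjoint_matrix.values.copy(), disjoint_matrix.meta.copy(), disjoint_matrix.totals.copy()
        )
        out = feature_set_comparison(disjoint_matrix, copy, cfg, split_spec=SplitSpec(seed=0))
        assert out["clusters"].accuracy == out["alternative"].accuracy

    def test_row_mismatch_rejected(self, disjoint_matrix):
        cfg = ModelConfig(grid=SMALL_GRID, n_estimators=10)
        sub = disjoint_matrix.subset_rows(list(disjoint_matrix.values.index[:-1]))
        with pytest.raises(ValueError, match="same rows"):
            feature_set_comparison(disjoint_matrix, sub, cfg)
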