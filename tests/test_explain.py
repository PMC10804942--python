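"""Additive attributions, feature ranking, heatmap ordering, embedding."""

import numpy as np
import pandas as pd
import pytest

import sensorscape as ss
from sensorscape.explain import (
    attribute,
    correlated_feature_group,
    embed,
    export_class_attributions,
    hierarchical_order,
    rank_features,
)
from sensorscape.models import ModelConfig, SensorProfileRegressor, train_classifier
from sensorscape.profile import SensorProfileMatrix

CFG = ModelConfig(grid={"learning_rate": [0.1], "depth": [4], "l2_leaf_reg": [3.0]},
                  n_estimators=60)


def _matrix(values: pd.DataFrame, labels=None) -> SensorProfileMatrix:
    meta = pd.DataFrame(index=values.index)
    if labels is not None:
        meta["ecosystem"] = labels
    return SensorProfileMatrix(values, meta, pd.Series(1.0, index=values.index))


@pytest.fixture(scope="module")
def fitted(disjoint_matrix):
    model = train_classifier(disjoint_matrix.values, disjoint_matrix.meta["ecosystem"], CFG)
    return model, disjoint_matrix


class TestAttribute:
    def test_additivity_holds_for_every_sample_and_class(self, fitted):
        model, m = fitted
        rows = m.values.iloc[:10]
        t = attribute(model, rows)  # raises internally if local accuracy fails
        raw = model.raw_scores(rows)
        for si, sample in enumerate(rows.index):
            for ci, cls in enumerate(model.classes_):
                s = t.table[(t.table["sample"] == sample) & (t.table["class"] == str(cls))]["value"].sum()
                total = s + t.base.loc[sample, str(cls)]
                assert total == pytest.approx(raw[si, ci], rel=1e-6, abs=1e-9)

    def test_regressor_attributions_additive(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.random((60, 4)), columns=list("abcd"))
        y = 2.0 * X["b"]
        model = SensorProfileRegressor(n_estimators=40).fit(X, y)
        t = attribute(model, X.iloc[:5])
        recon = t.table.groupby("sample")["value"].sum() + t.base["target"]
        pred = pd.Series(model.predict(X.iloc[:5]), index=X.index[:5])
        assert np.allclose(recon.reindex(pred.index), pred, rtol=1e-6)

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            attribute(SensorProfileRegressor(), pd.DataFrame(np.zeros((2, 2))))


class TestRankFeatures:
    def test_dominant_planted_feature_is_first(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.random((80, 5)), columns=[f"C{i}" for i in range(5)])
        y = pd.Series(np.where(X["C3"] > 0.5, "hi", "lo"), index=X.index)
        model = train_classifier(X, y, CFG)
        t = attribute(model, X)
        assert rank_features(t, scope="global").index[0] == "C3"

    def test_class_and_global_agree_for_symmetric_binary(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.random((80, 4)), columns=[f"C{i}" for i in range(4)])
        y = pd.Series(np.where(X["C1"] > 0.5, "hi", "lo"), index=X.index)
        model = train_classifier(X, y, CFG)
        t = attribute(model, X)
        g = rank_features(t, scope="global")
        c = rank_features(t, scope="class", cls=str(model.classes_[1]))
        assert g.index[0] == c.index[0] == "C1"

    def test_all_zero_attributions_rank_by_id(self):
        table = pd.DataFrame(
            {"sample": ["s"] * 3, "class": ["a"] * 3,
             "feature": ["z", "m", "a"], "value": [0.0, 0.0, 0.0]}
        )
        t = ss.AttributionTable(table, pd.DataFrame({"a": [0.0]}, index=["s"]), ["z", "m", "a"])
        assert list(rank_features(t).index) == ["a", "m", "z"]

    def test_signed_option(self):
        table = pd.DataFrame(
            {"sample": ["s", "s"], "class": ["a", "a"],
             "feature": ["f", "g"], "value": [0.5, -0.6]}
        )
        t = ss.AttributionTable(table, pd.DataFrame({"a": [0.0]}, index=["s"]), ["f", "g"])
        assert rank_features(t, signed=True).index[0] == "g"


class TestHierarchicalOrder:
    def test_identical_rows_adjacent_at_zero_height(self):
        values = pd.DataFrame(
            [[0.1, 0.5], [0.9, 0.0], [0.1, 0.5]],
            index=["a", "b", "c"], columns=["C0", "C1"],
        )
        rows, cols, links = hierarchical_order(_matrix(values))
        pos = {r: i for i, r in enumerate(rows)}
        assert abs(pos[0] - pos[2]) == 1  # the two identical rows are neighbours
        assert links["rows"][0, 2] == pytest.approx(0.0)  # first merge at height 0

    def test_block_structure_contiguous(self):
        rng = np.random.default_rng(0)
        block = np.kron(np.eye(2), np.ones((5, 4))) * 0.5 + rng.random((10, 8)) * 0.01
        values = pd.DataFrame(block, index=[f"s{i}" for i in range(10)],
                              columns=[f"C{i}" for i in range(8)])
        rows, _, _ = hierarchical_order(_matrix(values))
        first_block = {i for i in range(5)}
        positions = [rows.index(i) for i in range(10)]
        left = set(rows[:5])
        assert left == first_block or left == {5, 6, 7, 8, 9}

    def test_single_row_trivial(self):
        values = pd.DataFrame([[0.1, 0.2]], index=["only"], columns=["C0", "C1"])
        rows, cols, _ = hierarchical_order(_matrix(values))
        assert rows == [0] and sorted(cols) == [0, 1]

    def test_row_permutation_preserves_topology(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.random((8, 5)), index=[f"s{i}" for i in range(8)])
        m = _matrix(values)
        _, _, l1 = hierarchical_order(m)
        perm = list(values.index[::-1])
        _, _, l2 = hierarchical_order(_matrix(values.loc[perm]))
        assert np.allclose(np.sort(l1["rows"][:, 2]), np.sort(l2["rows"][:, 2]))


class TestEmbed:
    def test_same_seed_identical(self, disjoint_matrix):
        a = embed(disjoint_matrix, seed=0)
        b = embed(disjoint_matrix, seed=0)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_duplicated_rows_land_together(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(rng.random((20, 6)), index=[f"s{i}" for i in range(20)])
        dup = base.copy()
        dup.index = [f"d{i}" for i in range(20)]
        both = pd.concat([base, dup])
        coords = embed(_matrix(both), seed=0)
        diameter = np.ptp(coords.to_numpy(), axis=0).max()
        for i in range(20):
            d = np.linalg.norm(coords.loc[f"s{i}"] - coords.loc[f"d{i}"])
            assert d < 0.01 * diameter

    def test_separated_classes_have_high_silhouette(self, disjoint_matrix):
        from sklearn.metrics import silhouette_score

        coords = embed(disjoint_matrix, seed=0)
        score = silhouette_score(coords.to_numpy(), disjoint_matrix.meta["ecosystem"])
        assert score > 0.5

    def test_too_few_rows(self):
        values = pd.DataFrame([[0.1], [0.2]], index=["a", "b"], columns=["C0"])
        with pytest.raises(ValueError, match="at least 3"):
            embed(_matrix(values))


class TestCorrelatedFeatures:
    def test_duplicated_feature_is_top_hit(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.random((30, 4)), columns=["C0", "C1", "C2", "C3"])
        values["twin"] = values["C2"]
        out = correlated_feature_group(_matrix(values), "C2", k=1)
        assert list(out.index) == ["twin"] and out["twin"] == pytest.approx(1.0)

    def test_independent_features_weakly_correlated(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.random((200, 6)), columns=[f"C{i}" for i in range(6)])
        out = correlated_feature_group(_matrix(values), "C0", k=5)
        assert (out.abs() < 0.3).all()

    def test_k_zero_empty(self):
        values = pd.DataFrame(np.random.rand(10, 3), columns=["a", "b", "c"])
        assert correlated_feature_group(_matrix(values), "a", k=0).empty

    def test_constant_anchor_rejected(self):
        values = pd.DataFrame({"a": np.ones(10), "b": np.random.rand(10)})
        with pytest.raises(ValueError, match="constant"):
            correlated_feature_group(_matrix(values), "a", k=1)


def test_export_class_attributions(tmp_path, disjoint_matrix):
    labels = disjoint_matrix.meta["ecosystem"]
    model = train_classifier(disjoint_matrix.values, labels, CFG)
    t = attribute(model, disjoint_matrix.values.iloc[:8])
    cls = str(model.classes_[0])
    out = export_class_attributions(t, disjoint_matrix.values, cls, tmp_path / "f.tsv", top=3)
    assert (tmp_path / "f.tsv").exists()
    assert set(out.columns) == {"rank", "feature", "sample", "attribution", "feature_value"}
    assert out["rank"].max() <= 3
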