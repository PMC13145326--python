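import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from netmod import (
    CompositionTestError,
    ModulePartition,
    TraitTable,
    WeightedMatrix,
    categorical_composition_test,
    cwm,
    fdis,
    gower_distances,
    gower_space,
    module_consumer_weights,
    module_cwm,
    module_fdis,
)
from _oracles import gower_oracle


def _table(records, types):
    df = pd.DataFrame(records, index=[f"sp{i}" for i in range(len(records))])
    return TraitTable(data=df, types=types)


class TestGower:
    def test_identical_consumers_distance_zero(self):
        t = _table(
            [{"size": 1.0, "tooth": "conical"}, {"size": 1.0, "tooth": "conical"},
             {"size": 2.0, "tooth": "villiform"}],
            {"size": "quantitative", "tooth": "categorical"},
        )
        D = gower_distances(t)
        assert D.iloc[0, 1] == pytest.approx(0.0)

    def test_one_mismatch_in_k_traits(self):
        types = {f"t{i}": "categorical" for i in range(4)}
        recs = [
            {f"t{i}": "a" for i in range(4)},
            {**{f"t{i}": "a" for i in range(4)}, "t0": "b"},
        ]
        t = _table(recs, types)
        assert gower_distances(t).iloc[0, 1] == pytest.approx(1 / 4)

    def test_matches_hand_coded_oracle(self):
        rng = np.random.default_rng(0)
        types = {"size": "quantitative", "gape": "quantitative", "tooth": "categorical"}
        recs = [
            {"size": float(rng.normal()), "gape": float(rng.uniform(1, 3)),
             "tooth": rng.choice(["a", "b"])}
            for _ in range(5)
        ]
        t = _table(recs, types)
        np.testing.assert_allclose(
            gower_distances(t).to_numpy(), gower_oracle(recs, types), atol=1e-12
        )

    def test_zero_range_trait_excluded(self):
        t = _table(
            [{"size": 1.0, "flat": 2.0}, {"size": 3.0, "flat": 2.0}],
            {"size": "quantitative", "flat": "quantitative"},
        )
        with pytest.warns(UserWarning, match="flat"):
            D = gower_distances(t)
        assert D.iloc[0, 1] == pytest.approx(1.0)

    def test_embedding_reproduces_distances(self, planted_dataset):
        *_, traits = planted_dataset
        sp = gower_space(traits)
        emb = squareform(pdist(sp.coords))
        np.testing.assert_allclose(emb, sp.distances, atol=1e-8)
        # corrected distances differ from raw only by the additive constant
        off = ~np.eye(len(sp.labels), dtype=bool)
        np.testing.assert_allclose(
            sp.distances[off] - sp.raw_distances[off],
            sp.cailliez_constant,
            atol=1e-8,
        )


class TestFDis:
    def test_single_consumer_zero(self):
        assert fdis(np.array([[1.0, 2.0]]), np.array([3.0])) == 0.0

    def test_two_points_equal_weights(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert fdis(coords, np.array([1.0, 1.0])) == pytest.approx(2.5)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 3))
        w = rng.uniform(0.5, 2.0, size=6)
        centroid = (w[:, None] * X).sum(0) / w.sum()
        expected = sum(
            wi * np.sqrt(((xi - centroid) ** 2).sum()) for wi, xi in zip(w, X)
        ) / w.sum()
        assert fdis(X, w) == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance_and_scaling(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 2))
        w = rng.uniform(0.1, 1.0, size=5)
        base = fdis(X, w)
        theta = 0.7
        Rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        assert fdis(X @ Rot.T + np.array([5.0, -2.0]), w) == pytest.approx(base)
        assert fdis(3.0 * X, w) == pytest.approx(3.0 * base)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            fdis(np.zeros((2, 2)), np.array([0.0, 0.0]))


class TestModuleLevel:
    def test_consumer_set_spans_whole_network(self, planted_dataset):
        m, planted, *_ = planted_dataset
        w = module_consumer_weights(m, planted, 0)
        gr, _ = planted.indices_for(m)
        ri = np.flatnonzero(gr == 0)
        totals = m.values[ri].sum(axis=0)
        expected = {
            m.col_labels[j]: totals[j] for j in np.flatnonzero(totals > 0)
        }
        assert dict(w) == pytest.approx(expected)

    def test_single_user_module_fdis_zero(self):
        A = np.array([[4.0, 0.0], [0.0, 2.0], [0.0, 1.0]])
        m = WeightedMatrix(A, ["p0", "p1", "p2"], ["sp0", "sp1"])
        p = ModulePartition({"p0": 0, "sp0": 0, "p1": 1, "p2": 1, "sp1": 1})
        t = _table(
            [{"size": 1.0, "tooth": "a"}, {"size": 5.0, "tooth": "b"}],
            {"size": "quantitative", "tooth": "categorical"},
        )
        sp = gower_space(t)
        assert module_fdis(m, p, 0, sp) == pytest.approx(0.0)

    def test_trait_identical_users_fdis_zero(self):
        A = np.array([[2.0, 3.0], [1.0, 1.0]])
        m = WeightedMatrix(A, ["p0", "p1"], ["sp0", "sp1"])
        p = ModulePartition({"p0": 0, "p1": 1, "sp0": 0, "sp1": 1})
        t = _table(
            [{"size": 2.0, "tooth": "a"}, {"size": 2.0, "tooth": "a"},
             {"size": 7.0, "tooth": "b"}],
            {"size": "quantitative", "tooth": "categorical"},
        )
        sp = gower_space(t)
        # module 0's resources are used by sp0 and sp1, which share traits
        assert module_fdis(m, p, 0, sp) == pytest.approx(0.0, abs=1e-12)

    def test_abundance_weighting_flag(self, planted_dataset):
        m, planted, meta, _ = planted_dataset
        w_int = module_consumer_weights(m, planted, 1)
        w_ab = module_consumer_weights(
            m, planted, 1, weighting="abundance", abundance=meta.abundance
        )
        assert list(w_int.index) == list(w_ab.index)
        assert dict(w_ab) == {
            c: meta.abundance[c] for c in w_ab.index
        }


class TestCWM:
    def test_closed_forms(self):
        assert cwm([1, 3], [1, 1]) == pytest.approx(2.0)
        assert cwm([3, 0], [2, 1]) == pytest.approx(2.0)

    def test_convexity(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=10)
        w = rng.uniform(0, 5, size=10)
        w[0] = 1.0
        val = cwm(v, w)
        assert v.min() <= val <= v.max()

    def test_module_cwm_consistency(self, planted_dataset):
        m, planted, _, traits = planted_dataset
        vals = dict(traits.data["body_size"])
        w = module_consumer_weights(m, planted, 0)
        expected = sum(vals[c] * wi for c, wi in w.items()) / w.sum()
        assert module_cwm(m, planted, 0, vals) == pytest.approx(expected)


class TestComposition:
    def test_hand_evaluated_statistic(self):
        stat, df, p = categorical_composition_test(
            {"a": 10, "b": 0}, {"a": 0.5, "b": 0.5}
        )
        assert stat == pytest.approx(10.0)
        assert df == 1
        assert 0 < p < 0.01

    def test_proportional_observed_is_zero(self):
        stat, df, p = categorical_composition_test(
            {"a": 30, "b": 20, "c": 10}, {"a": 0.5, "b": 1 / 3, "c": 1 / 6}
        )
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_overrepresentation_detected(self):
        # one habitat used 3x its share at n = 60
        stat, df, p = categorical_composition_test(
            {"IL": 30, "CL": 10, "SC": 10, "MR": 10}, {k: 0.25 for k in ("IL", "CL", "SC", "MR")}
        )
        assert df == 3
        assert p < 0.05

    def test_zero_expected_with_observations_errors(self):
        with pytest.raises(CompositionTestError, match="merge"):
            categorical_composition_test({"a": 5, "b": 1}, {"a": 1.0, "b": 0.0})
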