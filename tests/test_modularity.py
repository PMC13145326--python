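import numpy as np
import pytest

from netmod import (
    DegenerateNormalizationError,
    ModulePartition,
    WeightedMatrix,
    bipartite_weighted_q,
    directed_weighted_q,
    find_modules,
    modularity_q,
    normalize_q,
)
from _oracles import exhaustive_best_q, modularity_oracle, random_valid_matrix


def _wm(A, kind="occurrence"):
    A = np.asarray(A, dtype=float)
    return WeightedMatrix(
        A, [f"r{i}" for i in range(A.shape[0])], [f"c{j}" for j in range(A.shape[1])],
        kind,
    )


def _part(m, gr, gc):
    d = {lab: g for lab, g in zip(m.row_labels, gr)}
    d.update({lab: g for lab, g in zip(m.col_labels, gc)})
    return ModulePartition(d)


class TestClosedForms:
    def test_identity_two_blocks(self):
        m = _wm(np.eye(2))
        p = _part(m, [0, 1], [0, 1])
        assert bipartite_weighted_q(m, p) == pytest.approx(0.5)
        assert directed_weighted_q(m, p) == pytest.approx(0.5)

    def test_single_module_is_zero(self):
        rng = np.random.default_rng(0)
        m = _wm(random_valid_matrix(rng, (4, 5)))
        p = _part(m, [0] * 4, [0] * 5)
        assert bipartite_weighted_q(m, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_pairs_directed(self):
        m = _wm([[1, 0], [0, 1]], kind="foodweb")
        p = _part(m, [0, 1], [0, 1])
        assert directed_weighted_q(m, p) == pytest.approx(0.5)

    def test_uncovered_node_errors(self):
        m = _wm(np.eye(2))
        p = ModulePartition({"r0": 0, "c0": 0, "r1": 1})
        with pytest.raises(KeyError, match="c1"):
            bipartite_weighted_q(m, p)


@pytest.mark.parametrize("seed", range(6))
def test_q_matches_brute_force_summation(seed):
    rng = np.random.default_rng(seed)
    A = random_valid_matrix(rng, (4, 4))
    m = _wm(A)
    gr = rng.integers(0, 3, size=4)
    gc = rng.integers(0, 3, size=4)
    ids = {g: k for k, g in enumerate(dict.fromkeys([*gr, *gc]))}
    p = _part(m, [ids[g] for g in gr], [ids[g] for g in gc])
    blocks = {}
    for i, g in enumerate(gr):
        blocks.setdefault(ids[g], []).append(("r", i))
    for j, g in enumerate(gc):
        blocks.setdefault(ids[g], []).append(("c", j))
    expected = modularity_oracle(A, list(blocks.values()))
    assert bipartite_weighted_q(m, p) == pytest.approx(expected, abs=1e-12)
    assert directed_weighted_q(m, p) == pytest.approx(expected, abs=1e-12)


def test_directed_equals_bipartite_on_this_carrier(small_matrix):
    """All edges run resource→consumer, so both formulas coincide."""
    rng = np.random.default_rng(1)
    gr = rng.integers(0, 3, size=small_matrix.shape[0])
    gc = rng.integers(0, 3, size=small_matrix.shape[1])
    p = _part(small_matrix, gr, gc)
    assert directed_weighted_q(small_matrix, p) == pytest.approx(
        bipartite_weighted_q(small_matrix, p), abs=1e-12
    )


class TestFindModules:
    def test_recovers_perfect_blocks(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 2
        A[3:, 3:] = 3
        m = _wm(A)
        p = find_modules(m, n_restarts=5, seed=0)
        q_star, _ = exhaustive_best_q(A)
        assert p.q == pytest.approx(q_star, abs=1e-10)
        assert p.n_modules == 2
        mods_a = {p.assignment[f"r{i}"] for i in range(3)}
        mods_b = {p.assignment[f"r{i}"] for i in range(3, 6)}
        assert len(mods_a) == 1 and len(mods_b) == 1 and mods_a != mods_b

    def test_all_ones_returns_single_module(self):
        m = _wm(np.ones((3, 3)))
        p = find_modules(m, n_restarts=3, seed=0)
        assert p.n_modules == 1
        assert p.q == pytest.approx(0.0, abs=1e-12)

    def test_stored_q_recomputable(self, planted_dataset):
        m, *_ = planted_dataset
        for method in ("simulated_annealing", "weighted_label_propagation"):
            p = find_modules(m, n_restarts=2, seed=3, method=method)
            assert modularity_q(m, p, "bipartite") == pytest.approx(p.q, abs=1e-10)

    def test_best_of_k_monotone_in_restarts(self, small_matrix):
        qs = [
            find_modules(small_matrix, n_restarts=k, seed=5,
                         method="weighted_label_propagation").q
            for k in (1, 2, 4, 8)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_deterministic_given_seed(self, small_matrix):
        p1 = find_modules(small_matrix, n_restarts=4, seed=9)
        p2 = find_modules(small_matrix, n_restarts=4, seed=9)
        assert p1.assignment == p2.assignment and p1.q == p2.q

    def test_module_ids_ordered_by_weight(self, planted_dataset):
        m, *_ = planted_dataset
        p = find_modules(m, n_restarts=2, seed=1, method="weighted_label_propagation")
        strength = dict(zip(m.row_labels, m.values.sum(axis=1)))
        strength.update(zip(m.col_labels, m.values.sum(axis=0)))
        totals = {}
        for lab, mod in p.assignment.items():
            totals[mod] = totals.get(mod, 0.0) + strength[lab]
        ordered = [totals[k] for k in sorted(totals)]
        assert ordered == sorted(ordered, reverse=True)


@pytest.mark.parametrize("shape", [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4)])
def test_optimizer_matches_exhaustive_search(shape):
    """On tiny matrices the stochastic search must hit the global optimum."""
    rng = np.random.default_rng(sum(shape))
    for _ in range(3):
        A = random_valid_matrix(rng, shape, max_weight=3)
        m = _wm(A)
        q_star, _ = exhaustive_best_q(A)
        for objective in ("bipartite", "directed"):
            p = find_modules(m, objective=objective, n_restarts=6, seed=17)
            assert p.q == pytest.approx(max(q_star, 0.0), abs=1e-10)


def test_merging_modules_never_beats_optimum():
    rng = np.random.default_rng(3)
    A = random_valid_matrix(rng, (4, 4), max_weight=3)
    m = _wm(A)
    p = find_modules(m, n_restarts=8, seed=2)
    ids = p.module_ids()
    for a in ids:
        for b in ids:
            if a >= b:
                continue
            merged = {
                lab: (a if g == b else g) for lab, g in p.assignment.items()
            }
            relabel = {g: k for k, g in enumerate(sorted(set(merged.values())))}
            pm = ModulePartition({lab: relabel[g] for lab, g in merged.items()})
            assert bipartite_weighted_q(m, pm) <= p.q + 1e-10


class TestNormalizeQ:
    def test_perfectly_modular_is_one(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 2
        A[3:, 3:] = 3
        m = _wm(A)
        p = _part(m, [0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1])
        assert normalize_q(m, p) == pytest.approx(1.0)

    def test_single_module_undefined(self):
        m = _wm(np.ones((3, 3)))
        p = _part(m, [0, 0, 0], [0, 0, 0])
        with pytest.raises(DegenerateNormalizationError):
            normalize_q(m, p)

    def test_synthetic_in_unit_interval(self, planted_dataset):
        m, planted, *_ = planted_dataset
        q = modularity_q(m, planted)
        nq = normalize_q(m, planted)
        assert 0 < nq <= 1
        assert nq >= q  # denominator Q_max ≤ 1
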