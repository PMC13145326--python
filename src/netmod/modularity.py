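"""Weighted modularity and module detection.

Two objectives over the same bipartite carrier:

* ``bipartite`` — Barber-style weighted bipartite modularity,
  ``Q = (1/W) * sum_{ij in same module} (A_ij - r_i c_j / W)``,
  used for occurrence networks;
* ``directed`` — weighted directed unipartite modularity for the food web
  viewed as a prey→predator graph,
  ``Q = sum_s [W_ss/W - (W_s_out/W)(W_s_in/W)]``.

Because every directed edge runs resource→consumer, a module's out-strength
is its row marginal total and its in-strength its column marginal total, so
the two objectives coincide numerically on this carrier; both are kept so
each network type is scored by the formula appropriate to it.

Optimization is stochastic (simulated annealing, the default, or a greedy
weighted label-propagation with merges); ``find_modules`` runs many restarts
and retains the best-scoring partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .matrix import WeightedMatrix, marginal_totals

Objective = Literal["bipartite", "directed"]

__all__ = [
    "ModulePartition",
    "bipartite_weighted_q",
    "directed_weighted_q",
    "modularity_q",
    "find_modules",
    "normalize_q",
    "DegenerateNormalizationError",
]


class DegenerateNormalizationError(ArithmeticError):
    """Q_max is zero: the network admits no modular structure to normalize by."""


@dataclass(frozen=True)
class ModulePartition:
    """A node→module assignment covering both sides of a matrix.

    ``assignment`` maps every row and column label to a module id; ids are
    contiguous from 0 and, when produced by :func:`find_modules`,
    canonicalized by descending module total weight.
    """

    assignment: Mapping[str, int]
    q: float = float("nan")
    n_modules: int = 0
    restarts_used: int = 0

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids and ids != list(range(len(ids))):
            raise ValueError(f"module ids must be contiguous from 0, got {ids}")
        if not self.n_modules:
            object.__setattr__(self, "n_modules", len(ids))

    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, module_id: int, labels) -> list[str]:
        return [x for x in labels if self.assignment[x] == module_id]

    def indices_for(self, m: WeightedMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Module index arrays (rows, cols); raises on uncovered nodes."""
        missing = [x for x in (*m.row_labels, *m.col_labels) if x not in self.assignment]
        if missing:
            raise KeyError(f"partition does not cover nodes: {missing}")
        gr = np.array([self.assignment[x] for x in m.row_labels], dtype=int)
        gc = np.array([self.assignment[x] for x in m.col_labels], dtype=int)
        return gr, gc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_label": list(self.assignment), "module_id": list(self.assignment.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, q: float = float("nan")) -> "ModulePartition":
        return cls(dict(zip(df["node_label"].astype(str), df["module_id"].astype(int))), q=q)


def _module_aggregates(m: WeightedMatrix, gr: np.ndarray, gc: np.ndarray):
    n_mod = int(max(gr.max(initial=-1), gc.max(initial=-1))) + 1
    r = marginal_totals(m, "rows")
    c = marginal_totals(m, "cols")
    Mr = np.zeros((len(gr), n_mod))
    Mr[np.arange(len(gr)), gr] = 1.0
    Mc = np.zeros((len(gc), n_mod))
    Mc[np.arange(len(gc)), gc] = 1.0
    within = np.einsum("is,ij,js->s", Mr, m.values, Mc)
    Rs = Mr.T @ r
    Cs = Mc.T @ c
    return within, Rs, Cs


def bipartite_weighted_q(m: WeightedMatrix, p: ModulePartition) -> float:
    """Barber weighted bipartite modularity of a given partition."""
    gr, gc = p.indices_for(m)
    W = m.total_weight
    within, Rs, Cs = _module_aggregates(m, gr, gc)
    return float(within.sum() / W - (Rs * Cs).sum() / W**2)


def directed_weighted_q(m: WeightedMatrix, p: ModulePartition) -> float:
    """Directed weighted modularity of the prey→predator view.

    Each module's out-strength is the summed out-strength (row totals) of
    its prey, its in-strength the summed in-strength (column totals) of its
    predators; there are no predator→prey edges.
    """
    gr, gc = p.indices_for(m)
    W = m.total_weight
    within, w_out, w_in = _module_aggregates(m, gr, gc)
    return float(sum(ws / W - (wo / W) * (wi / W) for ws, wo, wi in zip(within, w_out, w_in)))


def modularity_q(m: WeightedMatrix, p: ModulePartition, objective: Objective = "bipartite") -> float:
    return bipartite_weighted_q(m, p) if objective == "bipartite" else directed_weighted_q(m, p)


# -- optimizer internals ---------------------------------------------------
#
# Node index space: 0..R-1 rows, R..R+C-1 cols. State kept incrementally:
#   g[x]       module of node x
#   Rs[s], Cs[s]  summed row / column strength of module s
#   nmw[x, s]  weight of node x's edges into module s (opposite side only)
# Moving node x (strength s_x) from module a to b changes Q by
#   (nmw[x,b] - nmw[x,a]) / W - s_x * (opp[b] - opp[a]) / W**2
# where opp is Cs for row nodes and Rs for column nodes.


class _State:
    def __init__(self, m: WeightedMatrix, rng: np.random.Generator, init: str = "singletons"):
        A = m.values
        self.R, self.C = A.shape
        self.N = self.R + self.C
        self.W = m.total_weight
        self.A = A
        self.r = A.sum(axis=1)
        self.c = A.sum(axis=0)
        self.strength = np.concatenate([self.r, self.c])
        # adjacency of each node, indices in the 0..N-1 space
        self.nbr = [None] * self.N
        self.nbw = [None] * self.N
        for i in range(self.R):
            nz = np.flatnonzero(A[i])
            self.nbr[i] = nz + self.R
            self.nbw[i] = A[i, nz]
        for j in range(self.C):
            nz = np.flatnonzero(A[:, j])
            self.nbr[self.R + j] = nz
            self.nbw[self.R + j] = A[nz, j]
        self.n_slots = self.N
        if init == "singletons":
            self.g = np.arange(self.N)
        else:
            k = max(1, int(math.sqrt(self.N)))
            self.g = rng.integers(0, k, size=self.N)
        self.rebuild()

    def rebuild(self) -> None:
        g, ns = self.g, self.n_slots
        self.Rs = np.bincount(g[: self.R], weights=self.r, minlength=ns).astype(float)
        self.Cs = np.bincount(g[self.R:], weights=self.c, minlength=ns).astype(float)
        self.nmw = np.zeros((self.N, ns))
        for x in range(self.N):
            np.add.at(self.nmw[x], g[self.nbr[x]], self.nbw[x])
        within = sum(self.nmw[x, g[x]] for x in range(self.R))
        self.q = within / self.W - float(self.Rs @ self.Cs) / self.W**2

    def gain_vector(self, x: int) -> np.ndarray:
        """ΔQ of moving node x into every module slot (current slot → 0)."""
        a = self.g[x]
        opp = self.Cs if x < self.R else self.Rs
        dq = (self.nmw[x] - self.nmw[x, a]) / self.W - self.strength[x] * (opp - opp[a]) / self.W**2
        dq[a] = 0.0
        return dq

    def move_gain(self, x: int, b: int) -> float:
        a = self.g[x]
        if a == b:
            return 0.0
        opp = self.Cs if x < self.R else self.Rs
        return (self.nmw[x, b] - self.nmw[x, a]) / self.W - self.strength[x] * (opp[b] - opp[a]) / self.W**2

    def apply_move(self, x: int, b: int, dq: float) -> None:
        a = self.g[x]
        side = self.Rs if x < self.R else self.Cs
        side[a] -= self.strength[x]
        side[b] += self.strength[x]
        nbr = self.nbr[x]
        self.nmw[nbr, a] -= self.nbw[x]
        self.nmw[nbr, b] += self.nbw[x]
        self.g[x] = b
        self.q += dq

    def merge_gain(self, s: int, t: int) -> float:
        rows_s = np.flatnonzero(self.g[: self.R] == s)
        rows_t = np.flatnonzero(self.g[: self.R] == t)
        between = self.nmw[rows_s, t].sum() + self.nmw[rows_t, s].sum()
        return between / self.W - (self.Rs[s] * self.Cs[t] + self.Rs[t] * self.Cs[s]) / self.W**2

    def apply_merge(self, s: int, t: int, dq: float) -> None:
        """Merge module t into s."""
        self.g[self.g == t] = s
        self.Rs[s] += self.Rs[t]
        self.Cs[s] += self.Cs[t]
        self.Rs[t] = 0.0
        self.Cs[t] = 0.0
        self.nmw[:, s] += self.nmw[:, t]
        self.nmw[:, t] = 0.0
        self.q += dq

    def nonempty(self) -> np.ndarray:
        return np.flatnonzero((self.Rs > 0) | (self.Cs > 0) |
                              (np.bincount(self.g, minlength=self.n_slots) > 0))

    def empty_slot(self) -> int:
        counts = np.bincount(self.g, minlength=self.n_slots)
        empties = np.flatnonzero(counts == 0)
        return int(empties[0]) if empties.size else -1

    def split_proposal(self, rng: np.random.Generator):
        """Random bipartition of a random ≥2-node module; returns
        (members_to_move, target_slot, dq) or None."""
        counts = np.bincount(self.g, minlength=self.n_slots)
        cands = np.flatnonzero(counts >= 2)
        if cands.size == 0:
            return None
        u = self.empty_slot()
        if u < 0:
            return None
        s = int(rng.choice(cands))
        members = np.flatnonzero(self.g == s)
        mask = rng.random(members.size) < 0.5
        if not mask.any() or mask.all():
            return None
        moved = members[mask]
        mr = moved[moved < self.R]
        mc = moved[moved >= self.R] - self.R
        keep_r = np.setdiff1d(np.flatnonzero(self.g[: self.R] == s), mr)
        keep_c = np.setdiff1d(np.flatnonzero(self.g[self.R:] == s), mc)
        # lost within-weight: cross terms between moved and kept members
        lost = self.A[np.ix_(mr, keep_c)].sum() + self.A[np.ix_(keep_r, mc)].sum()
        R_m, C_m = self.r[mr].sum(), self.c[mc].sum()
        dq = -lost / self.W + (R_m * (self.Cs[s] - C_m) + C_m * (self.Rs[s] - R_m)) / self.W**2
        return moved, s, u, dq

    def apply_split(self, moved: np.ndarray, s: int, u: int, dq: float) -> None:
        mr = moved[moved < self.R]
        mc = moved[moved >= self.R] - self.R
        R_m, C_m = self.r[mr].sum(), self.c[mc].sum()
        self.g[moved] = u
        self.Rs[s] -= R_m
        self.Rs[u] += R_m
        self.Cs[s] -= C_m
        self.Cs[u] += C_m
        col_u = np.zeros(self.N)
        if mc.size:
            col_u[: self.R] += self.A[:, mc].sum(axis=1)
        if mr.size:
            col_u[self.R:] += self.A[mr, :].sum(axis=0)
        self.nmw[:, s] -= col_u
        self.nmw[:, u] += col_u
        self.q += dq


def _greedy_sweeps(st: _State, rng: np.random.Generator, tol: float = 1e-12) -> None:
    """Label-propagation sweeps plus greedy module merges until stable."""
    improved = True
    while improved:
        improved = False
        moved = True
        while moved:
            moved = False
            for x in rng.permutation(st.N):
                dq = st.gain_vector(x)
                b = int(np.argmax(dq))
                if dq[b] > tol:
                    st.apply_move(int(x), b, float(dq[b]))
                    moved = True
                    improved = True
        # greedy merges
        while True:
            mods = st.nonempty()
            if mods.size < 2:
                break
            best, best_dq = None, tol
            for ii in range(mods.size):
                for jj in range(ii + 1, mods.size):
                    dq = st.merge_gain(int(mods[ii]), int(mods[jj]))
                    if dq > best_dq:
                        best, best_dq = (int(mods[ii]), int(mods[jj])), dq
            if best is None:
                break
            st.apply_merge(best[0], best[1], best_dq)
            improved = True


def _anneal(st: _State, rng: np.random.Generator, cooling: float = 0.995) -> None:
    """Simulated annealing: node moves plus merge/split proposals.

    The starting temperature is calibrated from the spread of move gains so
    early random moves are mostly accepted; cooling is geometric; the run
    stops after N^2 consecutive rejected proposals (or a temperature floor),
    then finishes with greedy sweeps.
    """
    N = st.N
    samples = []
    for _ in range(min(64, 4 * N)):
        x = int(rng.integers(N))
        b = int(rng.integers(st.n_slots))
        samples.append(abs(st.move_gain(x, b)))
    scale = np.mean(samples) if samples else 1.0 / st.W
    t0 = max(scale, 1e-12) * 2.0
    t_floor = t0 * 1e-5
    t = t0
    rejected = 0
    stop_after = N * N
    n_merge_split = max(1, N // 10)
    while t > t_floor and rejected < stop_after:
        for _ in range(N):
            x = int(rng.integers(N))
            b = int(rng.integers(st.n_slots))
            if b == st.g[x]:
                rejected += 1
                continue
            dq = st.move_gain(x, b)
            if dq > 0 or rng.random() < math.exp(dq / t):
                st.apply_move(x, b, dq)
                rejected = 0
            else:
                rejected += 1
        for _ in range(n_merge_split):
            if rng.random() < 0.5:
                mods = st.nonempty()
                if mods.size >= 2:
                    s, u = rng.choice(mods, size=2, replace=False)
                    dq = st.merge_gain(int(s), int(u))
                    if dq > 0 or rng.random() < math.exp(dq / t):
                        st.apply_merge(int(s), int(u), dq)
                        rejected = 0
                    else:
                        rejected += 1
            else:
                prop = st.split_proposal(rng)
                if prop is not None:
                    moved, s, u, dq = prop
                    if dq > 0 or rng.random() < math.exp(dq / t):
                        st.apply_split(moved, s, u, dq)
                        rejected = 0
                    else:
                        rejected += 1
        t *= cooling
    _greedy_sweeps(st, rng)


def _canonical_assignment(m: WeightedMatrix, g: np.ndarray) -> dict[str, int]:
    """Relabel module ids by descending module total weight (ties: first
    appearance in row-then-column label order)."""
    labels = list(m.row_labels) + list(m.col_labels)
    r = m.values.sum(axis=1)
    c = m.values.sum(axis=0)
    strength = np.concatenate([r, c])
    totals: dict[int, float] = {}
    first_seen: dict[int, int] = {}
    for pos, mod in enumerate(g):
        mod = int(mod)
        totals[mod] = totals.get(mod, 0.0) + float(strength[pos])
        first_seen.setdefault(mod, pos)
    order = sorted(totals, key=lambda s: (-totals[s], first_seen[s]))
    relabel = {old: new for new, old in enumerate(order)}
    return {lab: relabel[int(mod)] for lab, mod in zip(labels, g)}


def find_modules(
    m: WeightedMatrix,
    objective: Objective = "bipartite",
    n_restarts: int = 100,
    seed: int = 0,
    method: Literal["simulated_annealing", "weighted_label_propagation"] = "simulated_annealing",
) -> ModulePartition:
    """Best-of-``n_restarts`` module detection; deterministic given ``seed``.

    Ties on Q (within 1e-12) break toward the lexicographically smallest
    canonical assignment, so reruns are reproducible bit for bit.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    R, C = m.shape
    if R + C <= 1:
        labels = list(m.row_labels) + list(m.col_labels)
        return ModulePartition({lab: 0 for lab in labels}, q=0.0, restarts_used=n_restarts)
    ss = np.random.SeedSequence(seed)
    best_q = -np.inf
    best_assign: dict[str, int] | None = None
    best_key: tuple | None = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        st = _State(m, rng)
        if method == "simulated_annealing":
            _anneal(st, rng)
        else:
            _greedy_sweeps(st, rng)
        st.rebuild()  # recompute q exactly, discarding incremental drift
        assign = _canonical_assignment(m, st.g)
        key = tuple(assign[lab] for lab in (*m.row_labels, *m.col_labels))
        if st.q > best_q + 1e-12 or (abs(st.q - best_q) <= 1e-12 and key < best_key):
            best_q, best_assign, best_key = st.q, assign, key
    # single-module degenerate outcome if nothing beats no structure
    part = ModulePartition(best_assign, q=float(best_q), restarts_used=n_restarts)
    if best_q <= 1e-12:
        labels = list(m.row_labels) + list(m.col_labels)
        part = ModulePartition({lab: 0 for lab in labels}, q=0.0, restarts_used=n_restarts)
        part = ModulePartition(part.assignment, q=modularity_q(m, part, objective),
                               restarts_used=n_restarts)
    return part


def normalize_q(m: WeightedMatrix, p: ModulePartition, objective: Objective = "bipartite") -> float:
    """Q divided by the Q of an idealized fully modular matrix.

    The ideal matrix keeps the partition's module marginal totals but moves
    all inter-module weight inside modules, giving each module within-weight
    (R_s + C_s)/2; its modularity Q_max bounds the observed Q from above.
    Raises :class:`DegenerateNormalizationError` when Q_max is zero (e.g. a
    single-module partition).
    """
    gr, gc = p.indices_for(m)
    W = m.total_weight
    _, Rs, Cs = _module_aggregates(m, gr, gc)
    q_max = float(((Rs + Cs) / 2.0).sum() / W - (Rs * Cs).sum() / W**2)
    if abs(q_max) < 1e-12:
        raise DegenerateNormalizationError(
            "Q_max is zero for this partition; normalized modularity undefined"
        )
    return modularity_q(m, p, objective) / q_max
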