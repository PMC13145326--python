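"""WNODA — weighted nestedness based on overlap and decreasing abundance.

For every within-side node pair ordered by marginal total (larger first),
the pair's nestedness degree is the percentage of the smaller-total node's
nonzero cells whose value is strictly lower than the corresponding cell of
the larger-total node, that corresponding cell being nonzero. Pairs with
equal marginal totals score 0 (the decreasing-abundance requirement).
WNODA is the joint mean over all row pairs and column pairs; it ranges from
0 (perfectly non-nested) to 100 (perfectly nested).

WNODA-SM restricts the computation to same-module matrix areas: only pairs
whose two nodes share a module contribute, and cell comparisons are limited
to the module's own resource × consumer block. With high modularity, a high
WNODA-SM indicates a compound (modular with internally nested modules)
topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import WeightedMatrix
from .modularity import ModulePartition

__all__ = [
    "NestednessResult",
    "UndefinedNestednessError",
    "wnoda",
    "wnoda_sm",
    "module_wnoda",
    "nestedness_summary",
]


class UndefinedNestednessError(ValueError):
    """The matrix (or module set) has no comparable node pair."""


@dataclass(frozen=True)
class NestednessResult:
    """Whole-matrix and same-module nestedness of one network."""

    wnoda_total: float
    wnoda_sm: float                   # pair-weighted across modules (primary)
    wnoda_sm_module_mean: float       # unweighted mean of per-module values
    per_module: dict[int, float]      # only modules with >1 consumer
    n_pairs_used: int


def _pair_score_sum(X: np.ndarray) -> tuple[float, int]:
    """Sum of pairwise nestedness scores over all row pairs of ``X`` and the
    pair count. Rows with no nonzero cell score 0 as the smaller member."""
    m = X.shape[0]
    if m < 2:
        return 0.0, 0
    totals = X.sum(axis=1)
    nz = np.count_nonzero(X > 0, axis=1).astype(float)
    Xu = X[:, None, :]
    Xv = X[None, :, :]
    count = ((Xv > 0) & (Xu > 0) & (Xv < Xu)).sum(axis=2)  # [u, v]
    larger = totals[:, None] > totals[None, :]             # u strictly larger than v
    safe_nz = np.where(nz > 0, nz, 1.0)
    score = 100.0 * count / safe_nz[None, :]
    score = np.where(nz[None, :] > 0, score, 0.0)
    return float(score[larger].sum()), m * (m - 1) // 2


def wnoda(m: WeightedMatrix | np.ndarray) -> float:
    """WNODA of a whole matrix, in [0, 100]."""
    X = m.values if isinstance(m, WeightedMatrix) else np.asarray(m, dtype=float)
    if X.shape[0] < 2 and X.shape[1] < 2:
        raise UndefinedNestednessError("need at least two rows or two columns")
    s_r, n_r = _pair_score_sum(X)
    s_c, n_c = _pair_score_sum(X.T)
    return (s_r + s_c) / (n_r + n_c)


def _module_blocks(m: WeightedMatrix, p: ModulePartition):
    gr, gc = p.indices_for(m)
    for mod in sorted(set(gr) | set(gc)):
        ri = np.flatnonzero(gr == mod)
        ci = np.flatnonzero(gc == mod)
        yield int(mod), ri, ci


def wnoda_sm(
    m: WeightedMatrix, p: ModulePartition, aggregation: str = "pair_weighted"
) -> float:
    """WNODA over same-module areas only.

    ``aggregation="pair_weighted"`` (default) pools pair scores across
    modules weighted by each module's contributing pair count;
    ``"module_mean"`` averages the per-module WNODA values instead.
    """
    total_score = 0.0
    total_pairs = 0
    per_module_vals = []
    for _, ri, ci in _module_blocks(m, p):
        block = m.values[np.ix_(ri, ci)]
        s_r, n_r = _pair_score_sum(block)
        s_c, n_c = _pair_score_sum(block.T)
        if n_r + n_c == 0:
            continue
        total_score += s_r + s_c
        total_pairs += n_r + n_c
        per_module_vals.append((s_r + s_c) / (n_r + n_c))
    if total_pairs == 0:
        raise UndefinedNestednessError("no module has more than one node on either side")
    if aggregation == "module_mean":
        return float(np.mean(per_module_vals))
    return total_score / total_pairs


def module_wnoda(m: WeightedMatrix, p: ModulePartition, module_id: int) -> float:
    """WNODA of one module's resource × consumer submatrix.

    Follows the convention of scoring only modules with more than one
    consumer; smaller modules raise :class:`UndefinedNestednessError`.
    """
    gr, gc = p.indices_for(m)
    ri = np.flatnonzero(gr == module_id)
    ci = np.flatnonzero(gc == module_id)
    if ci.size <= 1:
        raise UndefinedNestednessError(
            f"module {module_id} has {ci.size} consumer(s); WNODA skipped"
        )
    block = m.values[np.ix_(ri, ci)]
    s_r, n_r = _pair_score_sum(block)
    s_c, n_c = _pair_score_sum(block.T)
    return (s_r + s_c) / (n_r + n_c)


def nestedness_summary(m: WeightedMatrix, p: ModulePartition) -> NestednessResult:
    """Whole-matrix WNODA, both WNODA-SM aggregations and per-module values."""
    per_module: dict[int, float] = {}
    gr, gc = p.indices_for(m)
    for mod in sorted(set(gr) | set(gc)):
        if np.count_nonzero(gc == mod) > 1:
            per_module[int(mod)] = module_wnoda(m, p, int(mod))
    total_pairs = sum(
        r.size * (r.size - 1) // 2 + c.size * (c.size - 1) // 2
        for _, r, c in _module_blocks(m, p)
    )
    return NestednessResult(
        wnoda_total=wnoda(m),
        wnoda_sm=wnoda_sm(m, p),
        wnoda_sm_module_mean=wnoda_sm(m, p, aggregation="module_mean"),
        per_module=per_module,
        n_pairs_used=total_pairs,
    )
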