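"""Randomization schemes for weighted interaction matrices.

Three generators, all operating on integer "interaction events" (a cell of
weight k holds k events):

* ``vaznull`` — whole-network null preserving the number of nonzero cells
  exactly and the marginal totals probabilistically: a connectance skeleton
  is drawn cell by cell with probability proportional to the product of
  marginal totals (every row and column forced to receive at least one
  cell), then the remaining W − C events are spread over the skeleton with
  the same probabilities.
* ``module_constrained`` — the same procedure applied independently inside
  each module's diagonal block, leaving inter-module cells untouched; this
  keeps module membership fixed and is the reference for within-module
  nestedness.
* ``module_resample`` — Monte-Carlo null modules: a fixed number of events
  resampled (by default without replacement) from the whole network's event
  pool, used for the FDis and CWM nulls.

Matrices with non-integer cells are rescaled to integers by a power of ten
before event bookkeeping and scaled back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .matrix import WeightedMatrix
from .modularity import ModulePartition

__all__ = [
    "NullEnsemble",
    "InteractionSample",
    "InfeasibleNullError",
    "vaznull_replicate",
    "module_constrained_replicate",
    "module_resample",
    "build_ensemble",
]

Generator = Literal["vaznull", "module_constrained", "module_resample"]


class InfeasibleNullError(ValueError):
    """The constraints of the requested randomization cannot be satisfied."""


@dataclass(frozen=True)
class InteractionSample:
    """A multiset of resampled interaction events forming one null module."""

    events: pd.DataFrame  # columns: resource, consumer, weight (event counts)

    @property
    def n_events(self) -> int:
        return int(self.events["weight"].sum())

    def consumer_weights(self) -> pd.Series:
        """Total sampled events per consumer (the FDis/CWM weights)."""
        return self.events.groupby("consumer", sort=True)["weight"].sum()


@dataclass(frozen=True)
class NullEnsemble:
    replicates: Sequence[WeightedMatrix] | Sequence[InteractionSample]
    generator: Generator
    n: int
    base_seed: int


def _integer_events(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale cells to integers; returns (integer matrix, scale factor)."""
    for k in range(7):
        factor = 10.0**k
        scaled = values * factor
        if np.allclose(scaled, np.round(scaled), atol=1e-9):
            return np.round(scaled).astype(np.int64), factor
    raise InfeasibleNullError(
        "cells cannot be rescaled to integer interaction events (factor up to 1e6)"
    )


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of k items drawn without replacement, p ∝ weights (>0).

    Uses exponential-race keys, equivalent to sequential weighted draws;
    zero-weight items are never selected."""
    positive = np.flatnonzero(weights > 0)
    if positive.size < k:
        raise InfeasibleNullError(
            f"cannot draw {k} items from {positive.size} with positive weight"
        )
    keys = rng.exponential(size=positive.size) / weights[positive]
    if k == positive.size:
        return positive
    return positive[np.argpartition(keys, k - 1)[:k]]


def _vaznull_values(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Core vaznull on an integer matrix with no empty rows/cols."""
    R, C = A.shape
    r = A.sum(axis=1).astype(float)
    c = A.sum(axis=0).astype(float)
    n_links = int(np.count_nonzero(A))
    W = int(A.sum())
    if n_links < max(R, C):
        raise InfeasibleNullError(
            f"{n_links} links cannot cover {R} rows and {C} columns"
        )
    out = np.zeros((R, C), dtype=np.int64)
    # -- skeleton: force coverage first, pairing uncovered rows with
    #    uncovered columns so the minimum number of cells is spent
    unc_r = list(range(R))
    unc_c = list(range(C))
    while unc_r and unc_c:
        pr = r[unc_r] / r[unc_r].sum()
        pc = c[unc_c] / c[unc_c].sum()
        i = unc_r[rng.choice(len(unc_r), p=pr)]
        j = unc_c[rng.choice(len(unc_c), p=pc)]
        out[i, j] = 1
        unc_r.remove(i)
        unc_c.remove(j)
    for i in unc_r:  # rows still uncovered: every column already has a cell
        j = rng.choice(C, p=c / c.sum())
        out[i, j] = 1
    for j in unc_c:
        i = rng.choice(R, p=r / r.sum())
        out[i, j] = 1
    # -- fill the skeleton up to the observed link count
    used = int(out.sum())
    remaining = n_links - used
    if remaining > 0:
        p_cell = np.outer(r, c).ravel()
        p_cell[out.ravel() > 0] = 0.0
        picks = _weighted_sample_without_replacement(p_cell, remaining, rng)
        flat = out.ravel()
        flat[picks] = 1
        out = flat.reshape(R, C)
    # -- distribute the remaining events over the skeleton
    cells = np.flatnonzero(out.ravel())
    p = np.outer(r, c).ravel()[cells]
    extra = rng.multinomial(W - n_links, p / p.sum())
    flat = out.ravel()
    flat[cells] += extra
    return flat.reshape(R, C)


def vaznull_replicate(m: WeightedMatrix, seed) -> WeightedMatrix:
    """One connectance-preserving, degree-probabilistic replicate."""
    rng = np.random.default_rng(seed)
    A, factor = _integer_events(m.values)
    return m.with_values(_vaznull_values(A, rng) / factor)


def module_constrained_replicate(m: WeightedMatrix, p: ModulePartition, seed) -> WeightedMatrix:
    """vaznull applied inside each module's diagonal block only.

    Inter-module cells are copied unchanged; each block keeps its own link
    count and weight, so module membership stays valid in every replicate.
    """
    rng = np.random.default_rng(seed)
    A, factor = _integer_events(m.values)
    out = A.copy()
    gr, gc = p.indices_for(m)
    for mod in sorted(set(gr) | set(gc)):
        ri = np.flatnonzero(gr == mod)
        ci = np.flatnonzero(gc == mod)
        if ri.size == 0 or ci.size == 0:
            continue
        block = A[np.ix_(ri, ci)]
        # restrict to rows/cols active inside the block: inactive ones keep
        # their zeros and the coverage constraint stays feasible
        ar = np.flatnonzero(block.sum(axis=1) > 0)
        ac = np.flatnonzero(block.sum(axis=0) > 0)
        if ar.size == 0 or ac.size == 0 or block[np.ix_(ar, ac)].sum() == 0:
            continue
        sub = block[np.ix_(ar, ac)]
        try:
            rand = _vaznull_values(sub, rng)
        except InfeasibleNullError as err:
            raise InfeasibleNullError(f"module {mod}: {err}") from err
        new_block = np.zeros_like(block)
        new_block[np.ix_(ar, ac)] = rand
        out[np.ix_(ri, ci)] = new_block
    return m.with_values(out / factor)


def module_resample(
    m: WeightedMatrix,
    module_interaction_count: int,
    seed,
    *,
    replace: bool = False,
) -> InteractionSample:
    """Resample a null module of a given event count from the whole network.

    Events are drawn without replacement by default, so a null module is a
    sub-multiset of the observed network; consumers from any module can
    enter, which is the point of the null.
    """
    if module_interaction_count < 1:
        raise ValueError("module_interaction_count must be >= 1")
    rng = np.random.default_rng(seed)
    A, factor = _integer_events(m.values)
    W = int(A.sum())
    if not replace and module_interaction_count > W:
        raise InfeasibleNullError(
            f"cannot draw {module_interaction_count} events without replacement "
            f"from a network of {W}"
        )
    ri, ci = np.nonzero(A)
    counts = A[ri, ci]
    event_cell = np.repeat(np.arange(ri.size), counts)
    picks = rng.choice(event_cell.size, size=module_interaction_count, replace=replace)
    picked_cells = event_cell[picks]
    agg = np.bincount(picked_cells, minlength=ri.size)
    keep = np.flatnonzero(agg)
    df = pd.DataFrame(
        {
            "resource": [m.row_labels[i] for i in ri[keep]],
            "consumer": [m.col_labels[j] for j in ci[keep]],
            "weight": agg[keep] / factor,
        }
    )
    return InteractionSample(events=df)


def build_ensemble(
    generator: Generator,
    m: WeightedMatrix,
    p: ModulePartition | None = None,
    n: int = 1000,
    base_seed: int = 0,
    *,
    module_interaction_count: int | None = None,
    replace: bool = False,
) -> NullEnsemble:
    """n reproducible replicates with per-replicate seeds spawned from
    ``base_seed``; the same base seed yields a bit-identical ensemble."""
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(n)
    reps: list = []
    for child in children:
        if generator == "vaznull":
            reps.append(vaznull_replicate(m, child))
        elif generator == "module_constrained":
            if p is None:
                raise ValueError("module_constrained requires a partition")
            reps.append(module_constrained_replicate(m, p, child))
        elif generator == "module_resample":
            if module_interaction_count is None:
                raise ValueError("module_resample requires module_interaction_count")
            reps.append(module_resample(m, module_interaction_count, child, replace=replace))
        else:
            raise ValueError(f"unknown generator {generator!r}")
    return NullEnsemble(replicates=reps, generator=generator, n=n, base_seed=base_seed)
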