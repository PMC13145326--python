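"""Functional trait space and module-level assembly metrics.

The trait space is built from a mixed quantitative/categorical trait table
with Gower distances (range-normalized quantitative traits, simple matching
for categorical ones), embedded by principal coordinates with a Cailliez
additive correction when the distances are not Euclidean. Functional
dispersion (FDis) is the weighted mean distance of consumers to their
weighted centroid in that space; the community-weighted mean (CWM) is the
weighted mean of a quantitative trait. Both are evaluated per module
against Monte-Carlo null modules elsewhere in the package.

A module is characterized by its resources: the consumer set for FDis/CWM
is every consumer in the network that exploits the module's resources, with
weights given by that exploitation, which makes the metrics well defined
even for monospecific modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .matrix import WeightedMatrix
from .modularity import ModulePartition

__all__ = [
    "TraitTable",
    "GowerSpace",
    "gower_distances",
    "gower_space",
    "fdis",
    "module_consumer_weights",
    "module_fdis",
    "cwm",
    "module_cwm",
    "categorical_composition_test",
    "CompositionTestError",
]

TraitType = Literal["quantitative", "categorical"]


class CompositionTestError(ValueError):
    """Expected/observed categories are incompatible (merge guidance)."""


@dataclass(frozen=True)
class TraitTable:
    """Per-consumer traits with declared types, plus optional abundances.

    ``data`` is indexed by consumer label; ``types`` declares each column
    as quantitative or categorical.
    """

    data: pd.DataFrame
    types: Mapping[str, TraitType]
    abundance: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        undeclared = [t for t in self.data.columns if t not in self.types]
        if undeclared:
            raise ValueError(f"traits without declared type: {undeclared}")
        for trait, ttype in self.types.items():
            if trait not in self.data.columns:
                raise ValueError(f"declared trait {trait!r} missing from table")
            if ttype == "quantitative":
                vals = pd.to_numeric(self.data[trait])
                if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                    raise ValueError(f"non-finite values in quantitative trait {trait!r}")
            elif ttype != "categorical":
                raise ValueError(f"unknown trait type {ttype!r} for {trait!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate consumer labels in trait table")

    @property
    def consumers(self) -> list[str]:
        return [str(x) for x in self.data.index]

    def quantitative(self) -> list[str]:
        return [t for t, k in self.types.items() if k == "quantitative"]

    def categorical(self) -> list[str]:
        return [t for t, k in self.types.items() if k == "categorical"]

    def validate_against(self, m: WeightedMatrix) -> None:
        missing = [c for c in m.col_labels if c not in set(self.consumers)]
        if missing:
            raise ValueError(f"consumers missing from trait table: {missing}")

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, abundance=None) -> "TraitTable":
        """Build from long format with columns consumer/trait/value/type."""
        types = {}
        for trait, sub in df.groupby("trait", sort=False):
            declared = set(sub["type"])
            if len(declared) != 1:
                raise ValueError(f"trait {trait!r} declared with multiple types: {declared}")
            types[str(trait)] = next(iter(declared))
        wide = df.pivot(index="consumer", columns="trait", values="value")
        wide = wide[[t for t in types]]
        for t, k in types.items():
            if k == "quantitative":
                wide[t] = pd.to_numeric(wide[t])
        return cls(data=wide, types=types, abundance=abundance)


# -- Gower distances and principal-coordinates embedding -------------------

def gower_distances(t: TraitTable) -> pd.DataFrame:
    """Symmetric Gower distance matrix in [0, 1] over all consumers.

    Quantitative traits contribute |x−y|/range, categorical ones a 0/1
    mismatch; traits are equally weighted. Zero-range quantitative traits
    carry no information and are dropped with a warning.
    """
    n = len(t.data)
    if n < 2:
        raise ValueError("need at least two consumers")
    parts = []
    for trait, ttype in t.types.items():
        if ttype == "quantitative":
            v = t.data[trait].to_numpy(dtype=float)
            rng = v.max() - v.min()
            if rng == 0:
                warnings.warn(f"zero-range quantitative trait {trait!r} excluded")
                continue
            parts.append(np.abs(v[:, None] - v[None, :]) / rng)
        else:
            v = t.data[trait].to_numpy()
            parts.append((v[:, None] != v[None, :]).astype(float))
    if not parts:
        raise ValueError("no informative traits")
    D = np.mean(parts, axis=0)
    return pd.DataFrame(D, index=t.data.index, columns=t.data.index)


def _gower_center(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ M @ J


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean."""
    n = D.shape[0]
    d1 = _gower_center(-0.5 * D**2)
    d2 = _gower_center(-0.5 * D)
    block = np.block([[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]])
    eigvals = linalg.eigvals(block)
    return float(max(eigvals.real.max(), 0.0))


@dataclass(frozen=True)
class GowerSpace:
    """Distances and their principal-coordinates embedding."""

    labels: tuple[str, ...]
    raw_distances: np.ndarray
    distances: np.ndarray          # after Cailliez correction (if applied)
    coords: np.ndarray             # (n, k), axes with positive eigenvalues
    eigenvalues: np.ndarray
    cailliez_constant: float

    def coords_for(self, labels) -> np.ndarray:
        idx = [self.labels.index(str(x)) for x in labels]
        return self.coords[idx]


def gower_space(t: TraitTable, tol: float = 1e-8) -> GowerSpace:
    """Gower distances embedded into a Euclidean coordinate space.

    If the double-centered distance matrix has negative eigenvalues beyond
    tolerance, the Cailliez additive correction is applied first; all axes
    with positive eigenvalues are retained, so pairwise distances in the
    embedding reproduce the (corrected) Gower distances.
    """
    Ddf = gower_distances(t)
    D = Ddf.to_numpy()
    labels = tuple(str(x) for x in Ddf.index)

    def embed(Dm: np.ndarray):
        B = _gower_center(-0.5 * Dm**2)
        vals, vecs = linalg.eigh(B)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = embed(D)
    c = 0.0
    Dc = D
    if vals.min() < -tol * max(abs(vals).max(), 1.0):
        c = _cailliez_constant(D)
        Dc = D + c
        np.fill_diagonal(Dc, 0.0)
        vals, vecs = embed(Dc)
    keep = vals > tol * max(abs(vals).max(), 1.0)
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return GowerSpace(
        labels=labels,
        raw_distances=D,
        distances=Dc,
        coords=coords,
        eigenvalues=vals,
        cailliez_constant=c,
    )


# -- FDis and CWM ----------------------------------------------------------

def fdis(coords: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean distance to the weighted centroid.

    ``FDis = Σ w_i ||x_i − c|| / Σ w_i`` with ``c = Σ w_i x_i / Σ w_i``.
    A single consumer with positive weight gives 0 by convention.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if not total > 0:
        raise ValueError("weights must sum to a positive value")
    centroid = (w[:, None] * coords).sum(axis=0) / total
    dist = np.linalg.norm(coords - centroid, axis=1)
    return float((w * dist).sum() / total)


def module_consumer_weights(
    m: WeightedMatrix,
    p: ModulePartition,
    module_id: int,
    *,
    weighting: Literal["interaction", "abundance"] = "interaction",
    abundance: Mapping[str, float] | None = None,
) -> pd.Series:
    """Exploitation weights of *all* network consumers on one module.

    The consumer set is every consumer with at least one interaction with
    the module's resources (not only the module's members). The default
    weight is the consumer's total interaction weight with those resources;
    ``weighting="abundance"`` substitutes the consumer's global abundance
    while keeping the same consumer set.
    """
    gr, _ = p.indices_for(m)
    ri = np.flatnonzero(gr == module_id)
    if ri.size == 0:
        raise ValueError(f"module {module_id} has no resources")
    totals = m.values[ri].sum(axis=0)
    users = np.flatnonzero(totals > 0)
    if users.size == 0:
        raise ValueError(f"no consumer uses the resources of module {module_id}")
    labels = [m.col_labels[j] for j in users]
    if weighting == "interaction":
        w = totals[users]
    else:
        if abundance is None:
            raise ValueError("abundance weighting requires an abundance mapping")
        w = np.array([abundance[lab] for lab in labels], dtype=float)
    return pd.Series(w, index=labels, name="weight")


def module_fdis(
    m: WeightedMatrix,
    p: ModulePartition,
    module_id: int,
    space: GowerSpace,
    *,
    weighting: Literal["interaction", "abundance"] = "interaction",
    abundance: Mapping[str, float] | None = None,
) -> float:
    """FDis of the consumers exploiting one module's resources."""
    w = module_consumer_weights(
        m, p, module_id, weighting=weighting, abundance=abundance
    )
    return fdis(space.coords_for(w.index), w.to_numpy())


def cwm(values, weights) -> float:
    """Community-weighted mean: Σ w_i v_i / Σ w_i."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if not total > 0:
        raise ValueError("weights must sum to a positive value")
    return float((w * v).sum() / total)


def module_cwm(
    m: WeightedMatrix,
    p: ModulePartition,
    module_id: int,
    trait_values: Mapping[str, float],
    *,
    weighting: Literal["interaction", "abundance"] = "interaction",
    abundance: Mapping[str, float] | None = None,
) -> float:
    """CWM of a quantitative trait over a module's consumer set."""
    w = module_consumer_weights(
        m, p, module_id, weighting=weighting, abundance=abundance
    )
    vals = [trait_values[lab] for lab in w.index]
    return cwm(vals, w.to_numpy())


# -- categorical composition -----------------------------------------------

def categorical_composition_test(
    observed_counts: Mapping[str, float],
    expected_proportions: Mapping[str, float],
) -> tuple[float, int, float]:
    """Pearson chi-square of observed counts against expected proportions.

    Returns ``(statistic, df, p)`` with ``df = categories − 1`` and an
    upper-tail p-value. A category with zero expected proportion but
    positive observed count is unresolvable and raises
    :class:`CompositionTestError` suggesting a merge.
    """
    cats = list(observed_counts)
    O = np.array([observed_counts[k] for k in cats], dtype=float)
    miss = [k for k in cats if k not in expected_proportions]
    if miss:
        raise CompositionTestError(f"categories without expected proportion: {miss}")
    prop = np.array([expected_proportions[k] for k in cats], dtype=float)
    if O.sum() <= 0:
        raise ValueError("observed counts must sum to a positive value")
    if not np.isclose(prop.sum(), 1.0, atol=1e-8):
        raise ValueError(f"expected proportions sum to {prop.sum():g}, not 1")
    bad = (prop == 0) & (O > 0)
    if bad.any():
        names = [cats[i] for i in np.flatnonzero(bad)]
        raise CompositionTestError(
            f"zero expected proportion with positive observations in {names}; "
            "merge these categories with a neighbouring one"
        )
    E = prop * O.sum()
    keep = prop > 0
    stat = float(((O[keep] - E[keep]) ** 2 / E[keep]).sum())
    df = int(keep.sum()) - 1
    return stat, df, float(stats.chi2.sf(stat, df))
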