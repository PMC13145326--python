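"""Synthetic weighted networks with planted structure.

These generators emulate the data-generating structure of a riverine
piscivore assemblage survey: a community × predator occurrence matrix with
spatial modules and habitat structure, a prey × predator food web with
trophic modules, ecomorphological traits partially determined by module
membership, and lognormal abundances that drive interaction event counts
(so degree scales with log abundance).

Default dimensions mirror the study system the package targets: a 149 × 17
occurrence matrix with 3010 events and seven planted modules, and a
113 × 17 food web with 1271 events and six modules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .matrix import WeightedMatrix, NodeMetadata, Kind
from .modularity import ModulePartition
from .traits import TraitTable

import pandas as pd

__all__ = [
    "SyntheticSpec",
    "occurrence_like_spec",
    "foodweb_like_spec",
    "lognormal_abundances",
    "generate_modular_network",
    "generate_traits",
    "generate_neutral_network",
    "generate_study_like_dataset",
]

_HABITATS = ("IL", "CL", "SC", "MR")
_PREY_CATEGORIES = (
    "Characiformes",
    "Siluriformes",
    "Gymnotiformes",
    "Perciformes",
    "other fish orders",
    "invertebrates",
    "fish remains",
    "plant remains",
)

_QUANT_TRAITS = (
    "body_size",
    "body_size_sd",
    "caudal_fin_aspect_ratio",
    "body_elongation",
    "peduncle_compression",
    "eye_diameter_ratio",
    "eye_position_index",
    "oral_gape_ratio",
)
_CAT_TRAITS = ("tooth_shape", "pigmentation", "oral_gape_position", "habitat_guild")
_CAT_LEVELS = {
    "tooth_shape": ("conical", "triangular", "villiform"),
    "pigmentation": ("plain", "striped", "spotted"),
    "oral_gape_position": ("superior", "terminal", "inferior"),
    "habitat_guild": ("pelagic", "benthopelagic", "benthic"),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one planted-structure network.

    ``mixing`` is the probability that an interaction event lands outside
    its consumer's module; ``nestedness`` in [0, 1] sets how strongly
    intra-module cell probabilities decay with resource rank (0 = flat,
    1 = steep rank decay producing nested blocks); ``trait_convergence``
    in [0, 1] shrinks within-module trait variance.
    """

    n_resources: int = 149
    n_consumers: int = 17
    n_modules: int = 7
    mixing: float = 0.15
    nestedness: float = 0.5
    trait_convergence: float = 0.7
    abundance_log_mean: float = 4.0
    abundance_log_sd: float = 1.0
    total_events: int = 3010
    kind: Kind = "occurrence"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must be in [0, 1]")
        if not 0.0 <= self.nestedness <= 1.0:
            raise ValueError("nestedness must be in [0, 1]")
        if not 0.0 <= self.trait_convergence <= 1.0:
            raise ValueError("trait_convergence must be in [0, 1]")
        if self.n_resources < self.n_modules or self.n_consumers < self.n_modules:
            raise ValueError("each side needs at least one node per module")
        if self.total_events < self.n_resources + self.n_consumers:
            raise ValueError(
                "total_events must cover one event per resource and consumer"
            )


def occurrence_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Community × predator occurrence network at the study's scale."""
    return replace(SyntheticSpec(seed=seed), **overrides)


def foodweb_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Prey × predator food web at the study's scale."""
    base = SyntheticSpec(
        n_resources=113,
        n_consumers=17,
        n_modules=6,
        total_events=1271,
        kind="foodweb",
        seed=seed,
    )
    return replace(base, **overrides)


def lognormal_abundances(
    n: int, log_mean: float = 4.0, log_sd: float = 1.0, seed=0
) -> np.ndarray:
    """Positive integer abundances from a lognormal, at least 1 each."""
    rng = np.random.default_rng(seed)
    return np.maximum(1, np.round(rng.lognormal(log_mean, log_sd, size=n))).astype(int)


def _nested_profile(
    n_resources: int, n_consumers: int, strength: float
) -> np.ndarray:
    """Per-consumer resource weights producing nested within-module blocks.

    Consumers are ranked (0 = most generalist); consumer t reaches a
    resource prefix of length P_t that shrinks with t, so low-rank
    consumers' resource sets nest inside high-rank ones'. ``strength``
    interpolates between a flat profile (0, no structure beyond marginals)
    and hard nested prefixes (1). Returns an (n_consumers, n_resources)
    weight array; row 0 always reaches every resource.
    """
    w = np.full((n_consumers, n_resources), 1.0)
    if strength <= 0 or n_resources < 2:
        return w
    ranks = np.arange(n_resources, dtype=float)
    for t in range(n_consumers):
        prefix = max(1, round(n_resources * (n_consumers - t) / n_consumers))
        decay = np.maximum(0.0, (prefix - ranks) / prefix)  # triangular in rank
        w[t] = (1.0 - strength) + strength * decay
    return w


def _split_into_modules(n: int, n_modules: int, rng: np.random.Generator) -> np.ndarray:
    """Random assignment with every module non-empty, sizes near-equal."""
    base = np.repeat(np.arange(n_modules), np.diff(np.linspace(0, n, n_modules + 1).astype(int)))
    rng.shuffle(base)
    return base


def generate_modular_network(
    spec: SyntheticSpec,
) -> tuple[WeightedMatrix, ModulePartition, NodeMetadata]:
    """Plant a modular (optionally internally nested) weighted network.

    Every resource and consumer receives one guaranteed intra-module event
    (so the matrix has no empty nodes), then the remaining events pick a
    consumer with probability proportional to abundance and a resource
    inside the consumer's module with probability 1 − mixing (rank-decay
    weighted) or uniformly anywhere otherwise.

    Returns the matrix, the planted partition and metadata holding habitat
    labels (one habitat dominating each spatial module) and abundances.
    """
    rng = np.random.default_rng(spec.seed)
    R, C = spec.n_resources, spec.n_consumers
    res_mod = _split_into_modules(R, spec.n_modules, rng)
    con_mod = _split_into_modules(C, spec.n_modules, rng)
    abund = lognormal_abundances(
        C, spec.abundance_log_mean, spec.abundance_log_sd, rng
    ).astype(float)

    res_by_mod = [np.flatnonzero(res_mod == s) for s in range(spec.n_modules)]
    con_by_mod = [np.flatnonzero(con_mod == s) for s in range(spec.n_modules)]
    # per-consumer intra-module resource weights: nested prefixes keyed to
    # abundance rank (most abundant consumer is the block's generalist)
    intra_w = np.zeros((C, R))
    for s in range(spec.n_modules):
        cons, ress = con_by_mod[s], res_by_mod[s]
        profile = _nested_profile(ress.size, cons.size, spec.nestedness)
        order = np.argsort(-abund[cons], kind="stable")
        for t, jj in enumerate(order):
            intra_w[cons[jj], ress] = profile[t]

    A = np.zeros((R, C), dtype=np.int64)
    # coverage: one intra-module event per resource and per consumer
    for s in range(spec.n_modules):
        cons, ress = con_by_mod[s], res_by_mod[s]
        for i in ress:
            pw = abund[cons] * intra_w[cons, i]
            A[i, rng.choice(cons, p=pw / pw.sum())] += 1
        for j in cons:
            pw = intra_w[j, ress]
            A[rng.choice(ress, p=pw / pw.sum()), j] += 1

    remaining = spec.total_events - R - C
    per_consumer = rng.multinomial(remaining, abund / abund.sum())
    for j, n_j in enumerate(per_consumer):
        if n_j == 0:
            continue
        n_in = rng.binomial(n_j, 1.0 - spec.mixing)
        ress = res_by_mod[con_mod[j]]
        if n_in and ress.size:
            pw = intra_w[j, ress]
            A[ress, j] += rng.multinomial(n_in, pw / pw.sum())
        n_out = n_j - n_in
        if n_out:
            A[:, j] += rng.multinomial(n_out, np.full(R, 1.0 / R))

    prefix = "site" if spec.kind == "occurrence" else "prey"
    row_labels = [f"{prefix}{res_mod[i]}_{i:03d}" for i in range(R)]
    col_labels = [f"sp{j:02d}" for j in range(C)]
    m = WeightedMatrix(A, row_labels, col_labels, spec.kind)
    assignment = {lab: int(s) for lab, s in zip(row_labels, res_mod)}
    assignment.update({lab: int(s) for lab, s in zip(col_labels, con_mod)})
    partition = ModulePartition(assignment)
    categories = _HABITATS if spec.kind == "occurrence" else _PREY_CATEGORIES
    habitats = {
        lab: categories[res_mod[i] % len(categories)] for i, lab in enumerate(row_labels)
    }
    meta = NodeMetadata(
        row_category=habitats,
        abundance={lab: float(a) for lab, a in zip(col_labels, abund)},
    )
    return m, partition, meta


def generate_traits(
    partition: ModulePartition,
    consumers,
    convergence: float = 0.7,
    n_quant: int = 8,
    n_cat: int = 4,
    seed=0,
) -> TraitTable:
    """Ecomorphological traits partially determined by module membership.

    Quantitative trait values are ``c·μ_module + (1−c)·ε`` with module means
    μ drawn N(0, 1) and noise ε ~ N(0, 1), so ``convergence = 1`` gives zero
    within-module variance and ``convergence = 0`` module-independent
    traits. Categorical traits pick the module's preferred level with
    probability ``c`` and a uniform level otherwise.
    """
    if not 0.0 <= convergence <= 1.0:
        raise ValueError("convergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    consumers = [str(x) for x in consumers]
    mods = np.array([partition.assignment[c] for c in consumers])
    n_modules = int(mods.max()) + 1
    data: dict[str, object] = {}
    quant_names = [
        _QUANT_TRAITS[i] if i < len(_QUANT_TRAITS) else f"quant_trait_{i}"
        for i in range(n_quant)
    ]
    for name in quant_names:
        mu = rng.normal(0.0, 1.0, size=n_modules)
        eps = rng.normal(0.0, 1.0, size=len(consumers))
        data[name] = convergence * mu[mods] + (1.0 - convergence) * eps
    cat_names = [
        _CAT_TRAITS[i] if i < len(_CAT_TRAITS) else f"cat_trait_{i}"
        for i in range(n_cat)
    ]
    for name in cat_names:
        levels = _CAT_LEVELS.get(name, ("A", "B", "C"))
        preferred = rng.integers(0, len(levels), size=n_modules)
        draw = rng.random(len(consumers))
        uniform = rng.integers(0, len(levels), size=len(consumers))
        chosen = np.where(draw < convergence, preferred[mods], uniform)
        data[name] = [levels[k] for k in chosen]
    types = {n: "quantitative" for n in quant_names}
    types.update({n: "categorical" for n in cat_names})
    return TraitTable(
        data=pd.DataFrame(data, index=pd.Index(consumers, name="consumer")),
        types=types,
    )


def generate_neutral_network(
    abundances,
    n_resources: int,
    total_events: int,
    seed=0,
    *,
    resource_weights=None,
    kind: Kind = "occurrence",
) -> WeightedMatrix:
    """Abundance-only (neutral) network: no modules, no trait structure.

    Each event picks its consumer with probability proportional to
    abundance and its resource uniformly (or proportional to
    ``resource_weights``); one guaranteed event per node keeps the matrix
    free of empty rows/columns. Expected degree rises with abundance,
    reproducing the abundance–degree scaling of encounter-driven assembly.
    """
    rng = np.random.default_rng(seed)
    abund = np.asarray(abundances, dtype=float)
    if np.any(abund <= 0):
        raise ValueError("abundances must be positive")
    C = abund.size
    R = n_resources
    if total_events < R + C:
        raise ValueError("total_events must cover one event per node")
    rw = np.full(R, 1.0 / R) if resource_weights is None else (
        np.asarray(resource_weights, dtype=float) / np.sum(resource_weights)
    )
    pa = abund / abund.sum()
    A = np.zeros((R, C), dtype=np.int64)
    for i in range(R):
        A[i, rng.choice(C, p=pa)] += 1
    for j in range(C):
        A[rng.choice(R, p=rw), j] += 1
    remaining = total_events - R - C
    if remaining:
        p = np.outer(rw, pa).ravel()
        A += rng.multinomial(remaining, p).reshape(R, C)
    rows = [f"site_{i:03d}" for i in range(R)]
    cols = [f"sp{j:02d}" for j in range(C)]
    return WeightedMatrix(A, rows, cols, kind)


def generate_study_like_dataset(seed: int = 0, **overrides):
    """Occurrence network, food web, traits and metadata in one call.

    The two networks share consumers and traits; trait convergence follows
    the occurrence partition. Returns a dict with keys ``occurrence``,
    ``foodweb`` (each (matrix, planted partition, metadata)) and
    ``traits``.
    """
    ss = np.random.SeedSequence(seed)
    s_occ, s_fw, s_tr = ss.spawn(3)
    occ_spec = occurrence_like_spec(seed=s_occ, **overrides.get("occurrence", {}))
    fw_spec = foodweb_like_spec(seed=s_fw, **overrides.get("foodweb", {}))
    occ = generate_modular_network(occ_spec)
    fw = generate_modular_network(fw_spec)
    traits = generate_traits(
        occ[1],
        occ[0].col_labels,
        convergence=occ_spec.trait_convergence,
        seed=s_tr,
    )
    return {"occurrence": occ, "foodweb": fw, "traits": traits}
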