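"""z-scores, their ecological interpretation, and the end-to-end pipeline.

Every metric is compared with its null ensemble through the standardized
score ``z = (x_obs − mean(nulls)) / sd(nulls)``; |z| > 2 is treated as
significant. The sign maps to an ecological reading that depends on the
metric: high WNODA means a nested network, low FDis means niche filtering
(functional convergence), high CWM means trait matching, and so on.

``run_full_analysis`` executes the whole pipeline on an occurrence network
and a food web: module detection with restarts, normalized modularity and
its null z, whole-matrix and same-module WNODA z-scores, per-module WNODA
against membership-constrained nulls, per-module FDis and CWM against
resampled null modules, categorical composition chi-square tests, and the
abundance–degree regressions. The report is a plain JSON-serializable dict
with all seeds and replicate counts logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .matrix import WeightedMatrix, NodeMetadata, degree
from .modularity import (
    find_modules,
    normalize_q,
    DegenerateNormalizationError,
)
from .nestedness import (
    UndefinedNestednessError,
    wnoda,
    wnoda_sm,
    module_wnoda,
)
from .nulls import (
    build_ensemble,
    module_resample,
)
from .traits import (
    TraitTable,
    gower_space,
    fdis,
    cwm,
    module_consumer_weights,
    categorical_composition_test,
    CompositionTestError,
)

__all__ = [
    "ZScoreResult",
    "RegressionResult",
    "DegenerateNullError",
    "SIGNIFICANCE_THRESHOLD",
    "zscore",
    "abundance_degree_regression",
    "AnalysisConfig",
    "run_full_analysis",
]

SIGNIFICANCE_THRESHOLD = 2.0

# metric family → (reading when z > 2, reading when z < −2)
_INTERPRETATION = {
    "wnoda": ("nested", "anti-nested"),
    "wnoda_sm": ("nested", "anti-nested"),
    "modularity": ("modular", "anti-modular"),
    "fdis": ("limiting similarity", "niche filtering"),
    "cwm": ("trait matching", "trait barrier"),
}


class DegenerateNullError(ArithmeticError):
    """The null ensemble has zero spread; a z-score is undefined."""


@dataclass(frozen=True)
class ZScoreResult:
    metric: str
    x_obs: float
    null_mean: float
    null_sd: float
    z: float
    n_reps: int
    interpretation: str

    @property
    def significant(self) -> bool:
        return abs(self.z) > SIGNIFICANCE_THRESHOLD


def _interpret(metric: str, z: float) -> str:
    if abs(z) <= SIGNIFICANCE_THRESHOLD:
        return "non-significant"
    family = metric.split(":")[0]
    labels = _INTERPRETATION.get(family)
    if labels is None:
        return "non-significant" if abs(z) <= SIGNIFICANCE_THRESHOLD else "significant"
    return labels[0] if z > 0 else labels[1]


def zscore(x_obs: float, null_values: Sequence[float], metric: str = "") -> ZScoreResult:
    """Standardized deviation of an observed metric from its null ensemble.

    ``metric`` selects the interpretation family by its prefix before an
    optional colon, e.g. ``"fdis:module3"`` → FDis readings.
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 2:
        raise ValueError("need at least two null values")
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd == 0:
        raise DegenerateNullError(f"null ensemble for {metric or 'metric'} has zero sd")
    z = (x_obs - mean) / sd
    return ZScoreResult(
        metric=metric,
        x_obs=float(x_obs),
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        n_reps=int(nulls.size),
        interpretation=_interpret(metric, z),
    )


@dataclass(frozen=True)
class RegressionResult:
    r_squared: float
    f_statistic: float
    p_value: float
    n_points: int
    slope: float
    intercept: float


def abundance_degree_regression(abundance, deg) -> RegressionResult:
    """OLS of node degree on log10 abundance.

    Degree is the response and the logarithm of abundance the predictor,
    matching how the abundance–degree relationship is plotted; R², F and p
    are base-invariant, the slope is per decade of abundance.
    """
    a = np.asarray(abundance, dtype=float)
    d = np.asarray(deg, dtype=float)
    if a.size != d.size:
        raise ValueError("abundance and degree must have equal length")
    if a.size < 3:
        raise ValueError("need at least three consumers")
    if np.any(a <= 0):
        raise ValueError("abundances must be positive")
    x = np.log10(a)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log-abundance predictor")
    fit = sps.linregress(x, d)
    n = a.size
    r2 = fit.rvalue**2
    if r2 >= 1.0:
        f = math.inf
    else:
        f = r2 * (n - 2) / (1.0 - r2)
    return RegressionResult(
        r_squared=float(r2),
        f_statistic=float(f),
        p_value=float(fit.pvalue),
        n_points=int(n),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


# -- end-to-end pipeline ---------------------------------------------------

@dataclass
class AnalysisConfig:
    """Inputs and knobs for :func:`run_full_analysis`.

    Replicate counts are configurable; module detection inside network-level
    null replicates uses a reduced restart count and the faster greedy
    optimizer so the null ensemble stays tractable.
    """

    occurrence: WeightedMatrix | None = None
    foodweb: WeightedMatrix | None = None
    traits: TraitTable | None = None
    occurrence_meta: NodeMetadata | None = None
    foodweb_meta: NodeMetadata | None = None
    seed: int = 0
    n_restarts: int = 100
    n_null_network: int = 1000
    n_null_modules: int = 2000
    null_restarts: int = 20
    method: Literal["simulated_annealing", "weighted_label_propagation"] = (
        "simulated_annealing"
    )
    null_method: Literal["simulated_annealing", "weighted_label_propagation"] = (
        "weighted_label_propagation"
    )
    weighting: Literal["interaction", "abundance"] = "interaction"
    expected_proportions: Literal["species", "abundance"] = "species"


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _network_analysis(
    name: str,
    m: WeightedMatrix,
    objective: Literal["bipartite", "directed"],
    traits: TraitTable | None,
    meta: NodeMetadata | None,
    cfg: AnalysisConfig,
    seed_root: np.random.SeedSequence,
) -> dict:
    s_detect, s_vaz, s_con, s_mod = seed_root.spawn(4)
    stage = f"{name}: module detection"
    try:
        part = find_modules(
            m, objective=objective, n_restarts=cfg.n_restarts,
            seed=_seed_int(s_detect), method=cfg.method,
        )
    except Exception as err:  # pragma: no cover - stage label plumbing
        raise RuntimeError(f"stage failed: {stage}") from err
    out: dict = {
        "objective": objective,
        "n_rows": m.shape[0],
        "n_cols": m.shape[1],
        "total_weight": m.total_weight,
        "n_links": m.n_links,
        "q": part.q,
        "n_modules": part.n_modules,
        "restarts_used": part.restarts_used,
        "partition": dict(part.assignment),
    }
    try:
        out["normalized_q"] = normalize_q(m, part, objective)
    except DegenerateNormalizationError:
        out["normalized_q"] = None

    # network-level nulls: modularity and whole-matrix WNODA share the
    # vaznull ensemble; WNODA-SM uses the membership-constrained ensemble
    vaz = build_ensemble("vaznull", m, n=cfg.n_null_network, base_seed=_seed_int(s_vaz))
    null_q = []
    for k, rep in enumerate(vaz.replicates):
        null_part = find_modules(
            rep, objective=objective, n_restarts=cfg.null_restarts,
            seed=_seed_int(s_vaz) + k + 1, method=cfg.null_method,
        )
        null_q.append(null_part.q)
    out["modularity_z"] = asdict(zscore(part.q, null_q, metric="modularity"))

    out["wnoda"] = wnoda(m)
    null_wnoda = [wnoda(rep) for rep in vaz.replicates]
    out["wnoda_z"] = asdict(zscore(out["wnoda"], null_wnoda, metric="wnoda"))

    con = build_ensemble(
        "module_constrained", m, part, n=cfg.n_null_network, base_seed=_seed_int(s_con)
    )
    out["wnoda_sm"] = wnoda_sm(m, part)
    null_sm = [wnoda_sm(rep, part) for rep in con.replicates]
    out["wnoda_sm_z"] = asdict(zscore(out["wnoda_sm"], null_sm, metric="wnoda_sm"))

    # per-module analyses
    gr, gc = part.indices_for(m)
    space = None
    if traits is not None:
        traits.validate_against(m)
        space = gower_space(traits)
    abund_map = dict(meta.abundance) if meta is not None and meta.abundance else None
    modules_out: dict[str, dict] = {}
    event_total = m.total_weight
    for mod in sorted(set(gr) | set(gc)):
        mod = int(mod)
        entry: dict = {
            "n_resources": int((gr == mod).sum()),
            "n_consumers": int((gc == mod).sum()),
        }
        # within-module nestedness vs constrained nulls (>1 consumer only)
        try:
            obs_mw = module_wnoda(m, part, mod)
            null_mw = [module_wnoda(rep, part, mod) for rep in con.replicates]
            entry["wnoda"] = asdict(zscore(obs_mw, null_mw, metric=f"wnoda:module{mod}"))
        except (UndefinedNestednessError, DegenerateNullError) as err:
            entry["wnoda"] = {"skipped": str(err)}
        if space is not None and entry["n_resources"] > 0:
            ri = np.flatnonzero(gr == mod)
            count = m.values[ri].sum()
            count_int = max(1, int(round(count)))
            w_obs = module_consumer_weights(
                m, part, mod, weighting=cfg.weighting, abundance=abund_map
            )
            obs_fdis = fdis(space.coords_for(w_obs.index), w_obs.to_numpy())
            quant = traits.quantitative()
            obs_cwm = {
                t: cwm(
                    [traits.data.at[lab, t] for lab in w_obs.index], w_obs.to_numpy()
                )
                for t in quant
            }
            null_fdis, null_cwm = [], {t: [] for t in quant}
            mod_seed = np.random.SeedSequence(
                entropy=_seed_int(s_mod), spawn_key=(mod,)
            )
            for child in mod_seed.spawn(cfg.n_null_modules):
                sample = module_resample(m, count_int, child)
                cw = sample.consumer_weights()
                if cfg.weighting == "abundance" and abund_map is not None:
                    weights = np.array([abund_map[x] for x in cw.index])
                else:
                    weights = cw.to_numpy()
                null_fdis.append(fdis(space.coords_for(cw.index), weights))
                for t in quant:
                    null_cwm[t].append(
                        cwm([traits.data.at[lab, t] for lab in cw.index], weights)
                    )
            try:
                entry["fdis"] = asdict(zscore(obs_fdis, null_fdis, metric=f"fdis:module{mod}"))
            except DegenerateNullError as err:
                entry["fdis"] = {"x_obs": obs_fdis, "skipped": str(err)}
            entry["cwm"] = {}
            for t in quant:
                try:
                    entry["cwm"][t] = asdict(
                        zscore(obs_cwm[t], null_cwm[t], metric=f"cwm:{t}:module{mod}")
                    )
                except DegenerateNullError as err:
                    entry["cwm"][t] = {"x_obs": obs_cwm[t], "skipped": str(err)}
            # categorical trait composition: module members vs whole network
            entry["trait_chisq"] = {}
            members = [m.col_labels[j] for j in np.flatnonzero(gc == mod)]
            if members:
                for t in traits.categorical():
                    col = traits.data[t]
                    if cfg.expected_proportions == "abundance" and abund_map:
                        weights_all = np.array([abund_map[str(x)] for x in col.index])
                    else:
                        weights_all = np.ones(len(col))
                    levels = sorted(set(col))
                    expected = {
                        lv: float(weights_all[(col == lv).to_numpy()].sum())
                        for lv in levels
                    }
                    tot = sum(expected.values())
                    expected = {lv: v / tot for lv, v in expected.items()}
                    observed = {
                        lv: sum(1 for x in members if col.at[x] == lv) for lv in levels
                    }
                    try:
                        stat, df, p = categorical_composition_test(observed, expected)
                        entry["trait_chisq"][t] = {"statistic": stat, "df": df, "p": p}
                    except CompositionTestError as err:
                        entry["trait_chisq"][t] = {"skipped": str(err)}
        # habitat / prey-category representation of the module's resources,
        # event-weighted on both sides
        if meta is not None and meta.row_category:
            ri = np.flatnonzero(gr == mod)
            row_events = m.values.sum(axis=1)
            cats = sorted(set(meta.row_category[r] for r in m.row_labels))
            total_by_cat = {k: 0.0 for k in cats}
            for lab, ev in zip(m.row_labels, row_events):
                total_by_cat[meta.row_category[lab]] += ev
            tot = sum(total_by_cat.values())
            expected = {k: v / tot for k, v in total_by_cat.items()}
            observed = {k: 0.0 for k in cats}
            for i in ri:
                observed[meta.row_category[m.row_labels[i]]] += row_events[i]
            try:
                stat, df, p = categorical_composition_test(observed, expected)
                entry["composition_chisq"] = {"statistic": stat, "df": df, "p": p}
            except (CompositionTestError, ValueError) as err:
                entry["composition_chisq"] = {"skipped": str(err)}
        modules_out[str(mod)] = entry
    out["modules"] = modules_out

    # abundance–degree regression
    if abund_map is not None:
        deg = degree(m, "cols")
        abund = [abund_map[c] for c in m.col_labels]
        reg = abundance_degree_regression(abund, deg)
        out["abundance_degree"] = asdict(reg)
    return out


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Run the whole structural + assembly pipeline; deterministic per seed."""
    root = np.random.SeedSequence(cfg.seed)
    s_occ, s_fw = root.spawn(2)
    report: dict = {
        "config": {
            "seed": cfg.seed,
            "n_restarts": cfg.n_restarts,
            "n_null_network": cfg.n_null_network,
            "n_null_modules": cfg.n_null_modules,
            "null_restarts": cfg.null_restarts,
            "method": cfg.method,
            "null_method": cfg.null_method,
            "weighting": cfg.weighting,
        },
        "networks": {},
    }
    if cfg.occurrence is None and cfg.foodweb is None:
        raise ValueError("config must provide at least one network")
    if cfg.occurrence is not None:
        report["networks"]["occurrence"] = _network_analysis(
            "occurrence", cfg.occurrence, "bipartite", cfg.traits,
            cfg.occurrence_meta, cfg, s_occ,
        )
    if cfg.foodweb is not None:
        report["networks"]["foodweb"] = _network_analysis(
            "foodweb", cfg.foodweb, "directed", cfg.traits,
            cfg.foodweb_meta, cfg, s_fw,
        )
    return report
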