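# netmod

Structural and assembly analysis of weighted ecological networks:
modularity and nestedness against bespoke null models, plus module-level
trait-assembly inference for consumer assemblages.

The package targets a common design in community ecology: the same set of
consumers (here, a guild of piscivorous fishes) observed both in space —
a weighted **occurrence network** of community samples × species, cells
holding abundance counts — and in diet — a weighted **food web** of prey
items × predators, cells holding frequencies of prey occurrence in
stomachs. It answers three questions:

1. **Network structure.** Are the networks modular and/or nested beyond
   what connectance and degree distributions predict? Weighted bipartite
   (Barber-type) modularity `Q = (1/W) Σ_{ij∈same module} (A_ij − r_i c_j/W)`
   is optimized by simulated annealing with a best-of-restarts policy and
   reported alongside its normalization `Q/Q_max`; the food web uses the
   directed weighted form `Q = Σ_s [W_ss/W − (W_s^out/W)(W_s^in/W)]`.
   Nestedness uses WNODA (weighted nestedness based on overlap and
   decreasing abundance, 0–100), both whole-matrix and restricted to
   same-module areas (WNODA-SM). Significance comes from a Vázquez-style
   null model (connectance fixed exactly, degrees preserved
   probabilistically) and a module-membership-constrained variant, through
   `z = (x_obs − mean_null)/sd_null` with |z| > 2 as the decision rule.
2. **Module assembly.** For each module, functional dispersion (FDis,
   the abundance-weighted mean distance of consumers to their centroid in
   a Gower/PCoA trait space) and community-weighted means (CWM) of
   quantitative traits are scored against Monte-Carlo null modules that
   resample interaction events while preserving each module's event
   count. Low FDis means niche filtering (functional convergence), high
   FDis limiting similarity; CWM deviations mean trait matching or a
   trait barrier. Categorical trait and habitat/prey-category composition
   is tested with χ² contingency tests.
3. **Abundance-based assembly.** OLS of consumer degree on log10
   abundance (R², F, p) quantifies the neutral, encounter-driven
   component of network structure.

Because the field data this design comes from are deposited externally,
the package includes first-class synthetic generators that plant modules,
within-module nestedness, trait convergence and abundance–degree scaling
at the study's scale (149 × 17 occurrence matrix with 3010 events,
113 × 17 food web with 1271 events, 12 ecomorphological traits), so every
stage of the pipeline is testable end to end. See `docs/methods.md` for
the full model description and caveats.

## Worked example

```python
import netmod as nm
from netmod.synth import generate_study_like_dataset

data = generate_study_like_dataset(seed=42)
m, planted, meta = data["occurrence"]          # 149 x 17, W = 3010

part = nm.find_modules(m, objective="bipartite", n_restarts=20, seed=1)
print(f"Q = {part.q:.3f}  modules = {part.n_modules}")
print(f"normalized Q = {nm.normalize_q(m, part):.3f}")

ens = nm.build_ensemble("vaznull", m, n=100, base_seed=7)
z = nm.zscore(nm.wnoda(m), [nm.wnoda(r) for r in ens.replicates], metric="wnoda")
print(f"WNODA = {z.x_obs:.2f}  z = {z.z:+.2f}  ({z.interpretation})")

abund = [meta.abundance[c] for c in m.col_labels]
reg = nm.abundance_degree_regression(abund, nm.degree(m, "cols"))
print(f"degree ~ log10(abundance): R^2 = {reg.r_squared:.2f}, "
      f"F = {reg.f_statistic:.1f}, p = {reg.p_value:.2g}")
```

Output:

```
Q = 0.707  modules = 7
normalized Q = 0.851
WNODA = 13.31  z = -11.75  (anti-nested)
degree ~ log10(abundance): R^2 = 0.86, F = 89.7, p = 1e-07
```

Read: the optimizer recovers the seven planted spatial modules with high
modularity; the network is *less* nested than its degree distribution
predicts (the planted structure is modular, not nested); and degree
scales strongly with log abundance, the signature of encounter-driven
interaction accumulation.

The same analysis runs end to end — both networks, all null models,
per-module FDis/CWM/χ², regressions — via `nm.run_full_analysis`
(`nm.AnalysisConfig` holds the inputs, seeds and replicate counts), or
from the shell:

```sh
netmod simulate --seed 3 --out data/          # synthetic dataset as TSVs
netmod modules --matrix data/matrix.tsv --restarts 100 --seed 1
netmod assembly --matrix data/matrix.tsv --partition part.tsv \
    --traits data/traits.tsv --nulls 2000 --seed 1
netmod run --config analysis.yaml --out report.json
```

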