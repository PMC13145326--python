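# Methods

`netmod` analyses the structure and assembly of two kinds of weighted
ecological networks built from the same consumer assemblage: an
*occurrence network* (community samples × consumer species, cells =
abundance counts) and a *food web* (prey items × predators, cells =
frequency of occurrence in stomach contents). The pipeline asks three
questions: are the networks modular and/or nested beyond what abundance
and connectance alone predict; are modules assembled by trait-based
filters (functional convergence, trait matching) or by neutral
encounter probability; and does species degree scale with abundance.

## Data model

Both networks share one carrier, a labelled non-negative matrix with rows
as resources (communities or prey) and columns as consumers. Cells are
counts of "interaction events"; non-integer inputs are accepted but
rescaled to integers (by a power of ten) wherever events must be
redistributed. All-zero rows/columns are rejected by default — zero-degree
nodes break degree-probabilistic null models — with an explicit permissive
flag that drops them with a warning. Trait values enter at species level;
if individual-level measurements exist (e.g. body sizes), they are
collapsed to species means before building the trait table.

## Modularity

Two objectives over the same carrier:

* **Bipartite weighted modularity** (Barber-type), used for occurrence
  networks: `Q = (1/W) Σ_{ij in same module} (A_ij − r_i c_j / W)` with
  `r_i`, `c_j` the marginal totals and `W` the total weight.
* **Directed weighted modularity**, used for the food web viewed as a
  prey→predator graph: `Q = Σ_s [W_ss/W − (W_s^out/W)(W_s^in/W)]`.

Because every directed edge in this carrier runs resource→consumer, a
module's out-strength is its summed row totals and its in-strength its
summed column totals, so the two objectives coincide numerically here; a
property test pins this identity. Both are kept so each network type is
scored by the formula appropriate to it and so the directed form remains
correct if the carrier ever holds within-side edges.

**Optimization.** The default optimizer is simulated annealing over
node-move, module-merge and module-split proposals, with incremental
ΔQ bookkeeping (O(degree) per move). The schedule: the starting
temperature is calibrated to twice the mean |ΔQ| of random probe moves
(so early moves are mostly accepted), cooling is geometric with factor
0.995, each temperature level proposes N node moves plus ~N/10
merge/split moves, and a run stops after N² consecutive rejections or a
temperature floor of 1e−5 of the start, finishing with greedy sweeps.
A faster greedy alternative ("weighted label propagation": best-gain
sweeps from a singleton start plus exhaustive pairwise merges) is used
inside null ensembles where thousands of detections are needed.
`find_modules` runs `n_restarts` independent restarts (default 100,
matching common practice for stochastic modularity searches) and retains
the best Q; ties within 1e−12 break toward the lexicographically smallest
canonical assignment, and module ids are canonicalized by descending
module total weight, so results are bit-reproducible given a seed. On
matrices of ≤8 nodes the optimizer is tested against exhaustive search
over all set partitions.

**Normalization.** Raw Q is size- and connectance-dependent, so the
report includes `Q/Q_max`, where `Q_max` is the modularity of an
idealized fully modular matrix with the same module marginal totals:
each module's within-weight is replaced by `(R_s + C_s)/2`, which bounds
the attainable within-module weight and hence Q from above. A
single-module partition has `Q_max = 0` and normalization is reported as
undefined rather than coerced.

## Nestedness (WNODA)

For a within-side node pair ordered by marginal total (larger first), the
pair's nestedness degree is the percentage of the smaller-total node's
nonzero cells whose value is strictly lower than the corresponding
nonzero cell of the larger-total node. Pairs with equal marginal totals
contribute 0 (the decreasing-abundance requirement), and equal nonzero
cell values also score 0 — both are the conservative reading in the
weighted-NODF lineage; the tie rules are frozen here and pinned by an
independent pair-enumeration oracle in the tests. WNODA is the joint mean
over all row pairs and column pairs, in [0, 100]. It is invariant to
row/column permutation, to transposition, and to positive rescaling of
the matrix.

*WNODA-SM* restricts the computation to same-module areas: only pairs
sharing a module contribute, with comparisons confined to the module's
own resource × consumer block. Across modules the primary aggregation
weights each module by its contributing pair count; the unweighted
module mean is also reported. Per-module WNODA is computed for modules
with more than one consumer; smaller modules are skipped explicitly.

## Null models

* **vaznull** — preserves the number of nonzero cells exactly and the
  degree distribution probabilistically: a skeleton of exactly C cells is
  drawn with probability ∝ r_i·c_j, forcing every row and column to be
  covered (uncovered rows and columns are paired first, so the minimum
  number of cells is spent on coverage); the remaining W − C events are
  then distributed multinomially over the skeleton with the same
  probabilities. Used for whole-network modularity and WNODA z-scores.
* **module-constrained** — the same procedure applied independently
  inside each module's diagonal block, inter-module cells copied
  unchanged; membership stays fixed, so this is the reference for
  within-module and same-module nestedness.
* **module resampling** — null modules for FDis/CWM: a fixed number of
  events (the observed module's event count) drawn from the whole
  network's event pool, without replacement by default so a null module
  is a sub-multiset of the observed network (a with-replacement flag
  exists). Consumers from any module can enter, which is the point: weak
  resource barriers would admit outside consumers.

Ensembles derive per-replicate seeds from a base seed via seed-sequence
spawning; the same base seed reproduces an ensemble bit for bit.

## Module-level assembly metrics

The trait space is built once for the whole assemblage: Gower distances
(range-normalized quantitative traits, simple-matching categorical
traits, equal weights; zero-range traits dropped with a warning),
embedded by principal coordinates. If the distance matrix is not
Euclidean, the Cailliez additive constant is applied first and all axes
with positive eigenvalues are kept, so embedded distances reproduce the
corrected Gower distances exactly — truncating axes would silently change
every downstream FDis value.

A module is characterized by its resources. The consumer set for FDis
and CWM is **every** consumer interacting with the module's resources,
weighted by its total interaction weight with them (an
abundance-weighting flag substitutes global abundances over the same
consumer set). This makes the metrics well defined even for monospecific
modules. FDis is the weighted mean distance to the weighted centroid;
CWM the weighted mean of a quantitative trait. Both are scored against
2000 resampled null modules by default via `z = (x_obs − mean)/sd`, with
|z| > 2 significant and interpreted as:

| metric      | z > 2                | z < −2          |
|-------------|----------------------|-----------------|
| WNODA       | nested               | anti-nested     |
| WNODA-SM    | nested               | anti-nested     |
| modularity  | modular              | anti-modular    |
| FDis        | limiting similarity  | niche filtering |
| CWM         | trait matching       | trait barrier   |

Categorical composition is tested with Pearson χ² against expected
proportions taken from the whole network: species-weighted for trait
categories by default (an abundance-weighted flag exists, since "the
proportion in the whole network" is ambiguous between the two), and
event-weighted for habitat/prey-category representation of a module's
resources. A category with zero expected share but positive observations
raises an error suggesting a merge rather than returning an infinite
statistic.

## Abundance–degree relationship

Ordinary least squares of degree (count of nonzero cells per consumer) on
log10 abundance, reporting R², F(1, n−2), the two-sided p, slope and
intercept. Degree is the response, matching how the relationship is
conventionally plotted; R², F and p are invariant to the log base and to
the regression direction's rescaling of the slope.

## Synthetic data generator

The generators emulate the study system the package targets — a
floodplain-river piscivore assemblage — at its scale: 149 × 17
occurrence matrix with 3010 events and seven planted modules; 113 × 17
food web with 1271 events and six modules; 12 traits (8 quantitative,
4 categorical); lognormal abundances (log-mean 4, log-sd 1, i.e. median
~55 individuals with a long tail).

Events pick a consumer ∝ abundance and then a resource inside the
consumer's module with probability 1 − mixing (default 0.15, giving
strong but imperfect modules) or uniformly anywhere otherwise; one
intra-module event per node is guaranteed first so no node is empty.
Planted within-module nestedness acts on the interaction *support*:
consumers ranked by abundance receive nested resource prefixes with a
triangular within-prefix decay. This matters because a pure product-form
rank decay is exactly what a marginal-preserving null reproduces and
plants no detectable nestedness; the support-based construction yields
module WNODA z > 2 at strength 1. The default strength 0.5 leaves blocks
slightly *less* nested than their marginals predict, mirroring the weak
anti-nestedness typical of empirical occurrence networks of this kind.
Traits are `c·μ_module + (1 − c)·noise` with convergence c (default
0.7); c = 1 gives zero within-module variance, c = 0 module-independent
traits. A separate neutral generator (consumer ∝ abundance, resource
uniform) produces the abundance-only baseline in which degree scales
with log abundance.

What the generator does **not** emulate: temporal autocorrelation among
community samples, ontogenetic diet shifts, uneven taxonomic resolution
of prey, spatial distances between sites, and observation error in
stomach contents. Passing tests therefore demonstrate that the methods
recover planted structure of the stated kinds at realistic scale — not
that any particular field system has that structure.

## Statistical calibration — a caveat worth knowing

Two constructions inflate the |z| > 2 rule well above its nominal level,
and the calibration tests deliberately avoid them:

* comparing a matrix from one generative process (e.g. the neutral
  generator) against a vaznull ensemble confounds process mismatch with
  the tested hypothesis (measured WNODA rejection ≈ 24% on structureless
  data);
* scoring FDis/CWM on modules *detected* from the same matrix adds
  selection bias — detected modules concentrate weight by construction
  (measured rejection 40–60% with random traits).

The type-I experiments therefore score an observed draw of the same
randomization process against its ensemble, and use partitions
independent of the matrix for the trait metrics; measured rates are then
3–5% at the |z| > 2 rule. Users applying the pipeline to detected
modules should read borderline module-level z-values conservatively.

## Numerical choices and degenerate inputs

* z-scores use the sample sd (ddof = 1); a zero-sd ensemble raises an
  explicit degenerate-null error instead of returning ±inf.
* Stored partition Q is recomputed exactly from the assignment after
  optimization (tolerance 1e−10 in tests), discarding incremental
  floating drift.
* Single-node matrices return the trivial partition with Q = 0; a
  network with no beneficial split returns one module.
* A single-cell matrix has no WNODA (signalled); a module with ≤1
  consumer has no per-module WNODA (signalled).
* The vaznull skeleton is infeasible when links cannot cover all rows
  and columns; this raises an explicit error (it cannot occur for a
  validated matrix, but can for degenerate blocks passed directly).

## Problem sizes used by the bundled analyses

The acceptance script runs the full pipeline at the study's scale
(149 × 17 and 113 × 17) with 100 annealing restarts for the observed
networks, 200 network-level null replicates (greedy optimizer, 5
restarts, inside the ensemble) and 1000 module-level resamples — counts
chosen to keep Monte-Carlo error on reported z-scores small relative to
the |z| > 2 decision rule while completing in minutes. The test suite
uses smaller fixtures (tens of nodes, hundreds of events) whose expected
behaviour is pinned by closed forms and brute-force oracles.
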