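# Methods

## Data model

A survey couples a stem map (one row per tree: plot label, trunk x/y
in metres, DBH in cm, optional size traits) with two binary trees ×
species incidence layers — `nest` and `forage` — and a species
register carrying an `invasive` flag and an `exclude_from_spatial`
flag. All spatial statistics run on presence/absence; matrices holding
counts are binarized on load (with a warning) and the counts retained
only for abundance summaries. Coordinates are 2-D planar within-plot
metres; trunk-to-trunk Euclidean distance is the surrogate for
nest-to-nest distance (no canopy 3-D geometry), and plots are analysed
independently (no cross-plot distances). Stems under the 5 cm DBH
census rule warn rather than error, so partial or legacy tables load.

An **F-N record** is a (tree, species) pair with `forage = 1`,
`nest = 0` on that tree, and ≥ 1 nest of the species elsewhere in the
plot. Two conventions coexist deliberately:

- *tabulation* (`per_tree_richness(..., "fn")`): no exclusion flags
  applied — a ground-nesting super-colony with a few in-tree satellite
  nests still counts in the per-tree F-N column;
- *spatial* (`derive_fn_records`, default): species flagged
  `exclude_from_spatial` are dropped before both the observed and the
  null computation, because a ground-level colony's trunk positions do
  not measure canopy nest proximity.

## Diversity statistics

Trees are the sampling units; `Yᵢ` is the number of trees holding
species *i*, `q₁`/`q₂` the uniques/duplicates.

- **Mao Tau.** τ(h) = Σᵢ [1 − C(H−Yᵢ, h)/C(H, h)], the exact
  hypergeometric expectation of the sample-based accumulation curve.
  Binomials are evaluated through log-gamma with C(n, k) := 0 for
  k > n, so the curve is stable for plot-sized H. τ is nondecreasing
  and τ(H) = S_obs exactly.
- **Chao2.** Default is the classic form with the (H−1)/H
  small-sample factor, S_obs + A·q₁²/(2q₂); at q₂ = 0 it falls back
  (with a warning) to the bias-corrected form
  S_obs + A·q₁(q₁−1)/(2(q₂+1)). SDs come from the matching Chao-1987
  incidence variances; with q₁ = 0 the estimate is S_obs and the SD 0.
  Because the full-sample estimate does not depend on sample order,
  across-ordering randomization SDs collapse to zero at h = H;
  `chao2_accumulation` provides that EstimateS-style randomized curve
  separately, and the analytic variance is the full-sample
  uncertainty.
- **Per-tree richness** is reported as untransformed mean ± SE over
  all trees of a plot (ant-free trees count 0) for the layers `all`
  (union — a species nesting and foraging on one tree counts once),
  `nest`, `forage` and `fn`. Log-transformed ANOVA-style comparisons
  between plots are out of scope; the tables carry the summary
  statistics needed for them.

## Spatial null model

For each F-N record (t, s): the **nearest-nest distance** is
min over trees u ≠ t with nest(u, s) = 1 of d(t, u) — strictly
positive, always defined. The **cumulative curve** is the empirical
CDF of these distances on a 1 m grid (0–30 m by default, extended to
the maximum distance so it reaches 1). The **nesting-probability
profile** at radius d is

p(t, s, d) = #{u ≠ t : d(t,u) ≤ d, nest(u,s) = 1} / #{u ≠ t : d(t,u) ≤ d},

averaged over records with a nonzero denominator, for d = 5, 10, …,
30 m. Dividing by the local tree count corrects for tree density, so
plots with different stem packing are comparable. The focal tree is
excluded from numerator and denominator (it cannot hold a nest of an
F-N species by definition). The default mean weighs every (tree,
species) record equally; a per-tree-first averaging mode
(`per_tree=True`) is exposed for sensitivity analysis.

**Null distribution.** Only the nest layer is randomized; the F-N
record list stays at its observed value, so observed and null
computations are structurally identical (if a randomized nest lands on
a record's focal tree, the minimum is still taken over the other
trees; the vanishingly rare case of a single-nest species landing its
only nest on the focal tree yields an undefined record dropped from
that draw's mean). Randomization is quasiswap via **curveball
trades**: repeatedly pick two rows and redistribute the columns held
by exactly one of them uniformly between the two. Every draw preserves
all row and column sums exactly (asserted at runtime), mixes afresh
from the observed matrix with ≥ 10 × (number of 1s) trade attempts
(minimum 100), and is therefore independent of previous draws given
the margins. The margin constraint keeps empty trees and unrecorded
species empty. Uniformity over the margin class is verified in the
tests by exhaustive class enumeration on 4 × 4 matrices and
cross-checked against R vegan's `quasiswap` ensemble.

Holding both margins fixed is the scientific point: each species keeps
its observed number of nest trees (abundance) and each tree keeps its
observed number of nesting species (tree-size / quality effects), so
only the *spatial arrangement* of nests over trees is randomized.

**Envelopes and tests.** With n_perm = 100 (default; seed mandatory,
one master seed spawns independent per-draw substreams) the 2.5–97.5 %
envelope uses nearest-rank order statistics — the 3rd and 98th values
— and the min–max band is also emitted (some displays use one, some
the other). The observed mean is ranked within the null means:
two-sided empirical p = 2·min(r_low, r_high)/(n_perm + 1), so an
observed mean below all 100 null means gives p = 2/101 ≈ 0.02. A
rank-sum (Mann–Whitney) statistic of the observed mean against the
null means is reported alongside; the two are labelled separately
because they answer slightly different questions and neither is
claimed equivalent to any particular historical printout.

## Synthetic forest generator

Defaults describe one 40 × 80 m plot of 350 stems. Components, with
defaults and what they emulate:

- **Positions**: uniform, or a Thomas cluster process (10 parents,
  4 m offspring SD) for clumped stands. DBH = 5 + lognormal(μ=1.4,
  σ=0.8) cm: right-skewed, ≈ 60 % of stems ≤ 10 cm.
- **Nest occupancy**: per species k ~ log-series(p = 0.95), truncated
  at n_trees — one to three dominants and a long singleton tail.
  `nest_aggregation_sd` concentrates a species' nest trees around a
  random centre by exponential distance weighting (Gumbel top-k
  weighted sampling); `None` gives a uniform random subset, which
  makes the nest matrix uniform on its margin class — the regime used
  for calibration.
- **Foraging**: every nest marks its own tree; it reaches any other
  tree at distance d with probability `emission_rate ·
  exp(−d/kernel_range_m)` (defaults 0.12 and 5 m), independently per
  nest. `tourist_rate` (default 0.01) adds uniform per-(tree, species)
  foraging independent of nests, standing in for out-of-plot or
  ground-level colonies. Foraging is generated *from* nests, so
  recovering the kernel with the permutation test is a genuine
  inference problem rather than a round trip.

Two presets rehearse the study design: `primary-like` (389 stems, 102
species, kernel 3.5 m / emission 0.15 / tourists 0.003) and
`secondary-like` (295 stems, 50 species + a flagged ground-nesting
super-colony, kernel 9 m / emission 0.035 / tourists 0.01, log-series
p = 0.96). The kernel and rate values were chosen so the generated
communities match the field-scale descriptive statistics the presets
emulate (≈ 3.5–3.8 all-species per tree, ≈ 1.5 nesting species per
tree, ≈ 2 F-N species per tree, ≈ 80 % vs ≈ 60 % of F-N records
within 10 m, nesting probability near 10 % within 5 m) while keeping
the two plots' signal strengths distinct. `two_plot_study` draws both
plots with 26 species codes shared between their pools so shared-
species counts are meaningful. Everything is bit-reproducible from
(config, seed).

What the generator does *not* emulate: species nesting without any
foraging record (generated foraging always covers nest trees, so the
union layer equals the foraging layer and the union-layer rare-species
tail is thinner than in field data — Chao2 corrections on synthetic
unions are accordingly small); 3-D canopy connectivity; colony
identity or behavioural dominance; temporal dynamics. Passing tests
therefore certify the statistical machinery, not those biological
processes.

## Calibration and power (what the tests establish)

- *Type-I error.* With the kernel off and tourists only
  (tourist-only foraging ⟂ nests; uniform nest subsets), the observed
  statistic is exchangeable with the null draws, so with the 3rd/98th
  order-statistic envelope the exceedance probability is 6/101 ≈ 5.9 %.
  Over 200 simulated surveys the observed exceedance rate must fall in
  the exact binomial 99 % interval around that value. (The test sizes
  are 60 trees × 12 species with 100 permutations; the exchangeability
  argument, not the size, carries the result.)
- *Power.* With the kernel alone (emission 0.9, tourists 0) on
  80 trees × 15 species, a 5 m kernel must push the observed mean
  nearest-nest distance below the lower envelope in ≥ 90 % of 50
  replicates, and detection counts must be monotone in 1/λ over
  λ ∈ {2, 5, 15, 30} m. A nonzero fixed tourist rate would break the
  monotonicity at very short kernels — few kernel records, constant
  tourist dilution — which is why the power condition runs tourists
  off; with tourists the relevant quantity is the diluted mixture, not
  the kernel alone.

## Numerical and design choices

- Binomial coefficients in log space; distances via scipy `pdist`
  (exact to 1e-9 against a double loop).
- Envelope quantiles are nearest-rank order statistics, not
  interpolated quantiles: with 100 draws the bounds are observable
  values, and the exceedance probability is exactly computable.
- Degenerate inputs: a margin class of size 1 (no 2 × 2 checkerboard)
  returns the input matrix and collapses the envelope to a point;
  records with no tree inside a radius are skipped at that radius;
  an empty F-N record set raises rather than returning vacuous
  statistics.
- Randomization is per plot: each plot's nest matrix is permuted
  independently.
- CLI exit codes: 0 success, 2 configuration error, 3 data error;
  every output CSV gets a `*.meta.json` sidecar naming config hash,
  seed and package version.

## Known limitations

Trunk distance ignores crown overlap, so the spatial signal in
large-crowned stands is understated. The per-cell tourist rate is a
convenience parameterisation of "foragers unrelated to in-plot
nests"; it is not a mechanistic model of out-of-plot colonies. The
two-plot presets share the geometry (both uniform stem placement), so
between-plot differences in stem clumping are not reproduced. The
rank-sum comparison of one observed mean against 100 null means is
reported for completeness but carries little power beyond the rank p.
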