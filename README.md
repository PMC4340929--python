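# arborants

Diversity and spatial null-model analysis of arboreal ant communities
in tropical forest trees.

## The problem

Censusing every tree in a forest plot for ants yields, per tree, two
presence/absence record layers: species **nesting** in the tree and
species **foraging** on it. A large share of the species seen on any
one tree are *foraging-but-not-nesting* there (**F-N** records: the
species forages on the tree, holds no nest on it, but nests on at
least one other tree of the plot). The central question this package
addresses: **do F-N species nest closer in the surrounding trees than
expected if nests were distributed over trees at random?** If yes,
tree-level ant diversity is fed by an influx of foragers from
neighbouring canopies and is spatially dependent.

The package provides, for stem-mapped plot surveys (or synthetic
stand-ins with known structure):

- **Diversity statistics** with trees as sampling units: sample-based
  rarefaction via the analytic Mao Tau expectation
  `τ(h) = Σᵢ [1 − C(H−Yᵢ, h)/C(H, h)]`, the Chao2 incidence estimator
  `S_obs + ((H−1)/H) q₁²/(2q₂)` (classic and bias-corrected variants,
  Chao-1987 variances), per-tree richness by layer
  (all / nest / forage / F-N), shared species between plots, occupancy
  and abundance summaries.
- **Spatial statistics** on F-N records: nearest-nest distance per
  record, its empirical cumulative curve, and the nesting-probability
  profile `p(t,s,d)` = (nests of s within d of tree t) / (trees within
  d of t) averaged over records for d = 5, 10, …, 30 m — a
  density-corrected measure of how likely a forager's nest is nearby.
- **A fixed-marginal permutation null**: the nest matrix is randomized
  by quasiswap (curveball trades) holding every species' number of
  nest trees *and* every tree's number of nesting species constant;
  100 independent draws give 2.5–97.5 % envelopes, an empirical rank p
  and a rank-sum comparison of the observed mean against the null
  means.
- **A synthetic forest generator**: 40 × 80 m stem maps, log-series
  species abundances, spatially aggregated nests, and foraging grown
  from nests through an exponential distance-decay kernel — so the
  null model's power and calibration can be measured against known
  truth.

## Worked example

The analysis scripts run the whole pipeline on a synthetic two-plot
study whose presets emulate a 389-stem old-growth-like plot and a
295-stem regrowth-like plot (the latter with a ground-nesting
super-colony species excluded from spatial work):

```bash
python analysis/01_simulate.py --seed 1     # writes results/data/
python analysis/02_diversity.py             # writes results/diversity/
python analysis/03_spatial_null.py --seed 1 # writes results/spatial/
```

Output of the third step (seed 1):

```
primary: mean distance between all trees 32.8 m (SD 17.6)
  752 F-N records; 84% within 10 m of a conspecific nest
  observed mean nearest-nest distance 7.29 m vs null 12.30 m -> closer than random,
  outside the 95% envelope (rank p = 0.020)
  nesting probability within 5 m: observed 10.2% vs null 3.5% (outside envelope)

secondary: mean distance between all trees 32.3 m (SD 17.3)
  361 F-N records; 48% within 10 m of a conspecific nest
  observed mean nearest-nest distance 16.66 m vs null 16.82 m -> closer than random,
  inside the 95% envelope (rank p = 0.832)
  nesting probability within 5 m: observed 4.6% vs null 2.7% (outside envelope)
```

Reading: in the primary-like plot the average F-N record sits 7.3 m
from the nearest conspecific nest while fixed-marginal randomization
of the nest matrix predicts 12.3 m — foragers cluster around their
nests far more than chance, and the effect is outside the null
envelope at every radius. In the secondary-like plot (weaker kernel,
more uniform "tourist" foraging) the distance curve stays inside the
envelope and only the density-corrected probability at the closest
radius detects the signal — the same asymmetry the method is designed
to resolve.

A `arborants` console command exposes the same stages
(`simulate | diversity | nullmodel | all`) with a YAML config, and
`read_community()` loads any survey supplied as four CSVs (tree table
with coordinates, two trees × species incidence matrices, species
metadata with invasive / exclusion flags).

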