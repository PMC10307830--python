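# Methods

This note records the statistical procedures implemented in
`shrubrange`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data tests do and do not establish
about real data.

## Trait summaries

The atoms are individual trait measurements (species, trait, value,
provenance, coordinates) for plant height (m), specific leaf area
(mm²/mg) and seed mass (mg).  Cleaning is a fixed, order-pinned chain:

1. **Filter** — keep records that are georeferenced strictly above 30°N,
   or non-georeferenced but from a whitelisted high-latitude source;
   drop experimental treatments and herbarium specimens.  Malformed rows
   (non-positive values, impossible coordinates) are logged, never fatal.
   Each dropped row gets a single reason, with malformedness taking
   precedence over provenance, and provenance over geography.
2. **Deduplicate** — rows identical on (species, trait, value, latitude,
   longitude, collector) collapse to one.  The source database is not in
   the key: the same measurement deposited in two databases is one
   record.  Missing coordinates compare equal to missing coordinates.
3. **Trim** — within each species-by-trait group, drop rows further than
   4 sample SDs from the group mean.  Mean and SD come from the
   untrimmed group (single pass, not iterated): trimming is a screen for
   gross errors, not an estimator of the tail.  Singleton and zero-SD
   groups pass untouched.
4. **Minimum records** — groups with fewer than five rows are dropped
   and logged.

Retained groups are summarised as MTV = ln(median) and ITV = ln(sample
SD, n−1 denominator), both in log units of the trait's native unit;
species differences are better characterised on the log scale, and the
log transform makes both summaries exactly scale-equivariant
(multiplying raw values by c adds ln c to each).  A group whose SD is
exactly zero gets a missing ITV (not −∞) and is excluded from ITV
models with a logged warning.

Species lacking seed-mass summaries but holding both height and SLA are
gap-filled from genus-level seed-mass records georeferenced above 60°N,
when the pooled genus sample has at least five values; gap-filled
summaries carry confidence index 0.5.

**Confidence index.** Five records (or gap-filled) → 0.5; more than 20
→ 1; otherwise `0.33 + N/30`.  The linear rule is applied at exactly
N = 20 (giving 0.9967), which joins the endpoints continuously.  The
index is non-decreasing in N and bounded in [0.5, 1]; a species-level
combined index is the arithmetic mean of its per-trait indices.
Functional groups from maximum canopy height: dwarf (< 20 cm), low
(20–50 cm, both boundaries included), tall (> 50 cm).

## Range transforms and classification

Current range sizes (km²) are log-transformed and centred.  Projected
range shifts arrive as a species × scenario matrix (24 scenarios in the
emulated design) of absolute (km²) and relative (%) change.  For
regression, shifts are scaled (absolute by 10⁶ km², relative by 100), a
dataset-level constant c = −min(scaled) + 1 makes them positive, then
ln and centring.  The constant, the centring mean, and the transformed
image of zero raw change (`zero_reference = ln c − mean`) are stored so
fits can be read back on the original scale; c depends on the dataset
minimum, so subsets are re-transformed with their own constant.

Classification operates on **raw-scale** ensemble quantiles (linear
interpolation of order statistics, pinned because 24-point quantiles
differ across estimators): winner if the 25% quantile is strictly above
zero, loser if the 75% quantile is strictly below, otherwise no change —
a quantile exactly at zero reads as overlapping zero.  Because relative
change is a positive per-species rescaling of absolute change, the
category never depends on the absolute-vs-relative choice (property
tested over random ensembles).  Past categories use the same rule on
per-species cover-slope 95% intervals.

## Cover trends

Plot-level cover scores are ordinal counts in a nested site/subsite
design.  The package uses two-stage estimation: a Poisson log-linear
GLM of cover on centred year with subsite intercept dummies within each
species-by-site combination (≥3 distinct years, non-degenerate counts),
then precision-weighted pooling of site slopes to a species slope with
a normal 95% interval of the pooled mean.  Under the generative model
(Poisson counts, site/subsite intercept offsets, common species trend)
the two-stage estimator is unbiased for the trend and its intervals are
well calibrated (coverage checked by simulation at 30 sites × 20
years); a full hierarchical sampler could be swapped in behind the same
output contract.  Ordinal-link models are deliberately out of scope —
the Poisson approximation to ordinal cover scores is the pinned choice.

## Weighted Bayesian regression

Weights (confidence indices) multiply each observation's log-likelihood
contribution — an observation with weight 0.5 counts as half an
observation.  This is the convention of Bayesian regression packages
and differs from variance-scaling weights; on homoskedastic data,
down-weighting makes intervals conservative rather than anti-
conservative, which is the intended direction for low-confidence
records.

* **Gaussian** models use an exact conjugate normal–inverse-gamma
  posterior.  Priors are weakly informative: each coefficient has prior
  SD of 5 residual-SDs per SD of its predictor, the intercept 20
  residual-SDs, and the residual variance a near-flat inverse-gamma
  (a₀ = b₀ = 0.01).  Marginal posteriors are Student-t; with equal
  weights the posterior mean is within a fraction of a percent of
  ordinary least squares (oracle-tested at 1%).  The backend is closed
  form, hence deterministic, and flags convergence as exact.
* **Bernoulli** models (winner-vs-rest) use Normal(0, 2.5/sd(x)) priors
  on coefficients and Normal(0, 5) on the intercept — proper posteriors
  under complete separation — sampled with an affine-invariant ensemble
  MCMC (emcee; 24 walkers, 2500 steps, 1000 burn-in by default) started
  from the MAP.  Split-R̂ is computed per term across walkers; fits with
  max R̂ > 1.05 are marked non-converged.  Sampling is seeded, so fixed
  seeds give identical summaries.

An effect is a **clear relationship** when its 95% credible interval
excludes zero.  `run_model_suite` runs the full catalogue — univariate
MTV/ITV models for current range and each range-shift quantile, additive
and two-way-interaction three-trait models, categorical predictors
(deciduousness, functional group, dispersal mode, family), gains/losses
subsets (species with raw median change above/below zero, re-transformed
within the subset), cover-slope models, current-vs-future and
absolute-vs-relative consistency models, and the Bernoulli winner
models — logging each fit or a named skip in a manifest.  No
family-wise correction is applied, mirroring the analysis design; the
calibration tests quantify the ~5% of clear flags expected by chance
across a null suite.

## Ordination and permutation tests

PCA eigendecomposes the centred, unit-scaled species × trait matrix of
log-scale summaries (complete cases only).  Loading signs are arbitrary,
so the convention is pinned: the largest-magnitude loading of each
component is positive; cross-package comparisons should use absolute
loadings.  Scores × loadingsᵀ reconstructs the standardised matrix to
10⁻¹⁰ (tested).

PERMANOVA computes the pseudo-F on squared Euclidean distances,
`F = (SS_b/(g−1)) / (SS_w/(n−g))` with `SS_total = Σ_{i<j} d²_ij / n`,
against a null of uniformly permuted labels (no strata).  p-values use
the add-one estimator `(1 + #{F* ≥ F}) / (1 + permutations)`, so they
are never zero and are reproducible under a fixed seed; the sampled p
agrees with exhaustive enumeration on instances small enough to
enumerate (tested).  Dispersion homogeneity follows the
distance-to-centroid construction with a one-way ANOVA on the
distances; exactly equal group spreads are reported as F = 0, p = 1.
Pairwise PERMANOVAs adjust p-values by Holm or Bonferroni (or not at
all), delegated to statsmodels.

## Synthetic data: what it emulates, and what it does not

Trait values are lognormal — exp(Normal(log-median, log-spread)) — the
minimal law whose parameters are exactly the MTV/ITV targets on the log
scale.  Species-level log-medians are offset by a seeded
Normal(0, species_median_sd) and log-spreads by a lognormal multiplier
(σ = 0.3), so species differ the way real species do; setting both to
zero pins every species to the stated values.  Defaults emulate the
study's shape: 62 species × 3 traits × 96 records ≈ 17.9k records, a
24-member scenario ensemble, and 30 monitored sites.

Planted contaminants are appended as flagged extra rows and counted by
floor-plus-largest-remainder rounding of fraction × n (deterministic,
summing to round(fraction × total)).  Planted outliers sit at least 6
clean-group SDs above the mean, raised deterministically until they
exceed the 4-SD envelope of the *contaminated* group; because same-side
outliers inflate the group SD, this construction (and hence exact
removal) is feasible only for outlier fractions up to roughly
√(n/k) > 4.3, i.e. ~5% — the default is 1%.  At realistic trait
spreads a lognormal tail naturally produces occasional genuine > 4-SD
records, so the "cleaning removes exactly the planted rows" check runs
at a small log-spread (0.1) where the clean law has no mass near the
envelope, complemented by an oracle test at realistic spreads verifying
the trim removes precisely what brute-force recomputation flags.

Range ensembles: absolute change for species i in scenario s is
`10⁶ × (intercept + Σ_j β_j x_ij + ε_is)` km² with
ε ~ Normal(0, scenario_noise_sd); relative change divides by the
species' lognormal current range (defaults: ln-mean ln 5×10⁶ km²,
ln-SD 1).  The ground-truth β are therefore recovered by regressing the
raw median change (in 10⁶ km²) on the trait summary.  Defaults are a
null (intercept 0, no effects) with scenario noise SD 0.5 × 10⁶ km² —
the across-scenario spread is of the same order as typical mean shifts,
matching the strong between-scenario differences in ensemble
projections.  Cover counts are Poisson with seeded site/subsite
intercepts (SDs 0.3/0.2) and a per-species log-linear year trend.

None of the generators mimic spatial clustering of real trait records,
climate structure across scenarios, or ordinal cover-score truncation.
Passing tests therefore establish that the estimators are correct and
calibrated under the stated generative models — not that the
substantive ecological conclusions transfer to any particular real
dataset.

## Problem sizes and numerical choices

Calibration simulations use 100 replicates for coverage checks (planted
range-shift effect 0.5 at 200 species; Bernoulli slope 1.5 at n = 200;
cover trend 0.1/year at 30 sites × 20 years) and 200 replicates for
type-I checks (PERMANOVA at 199 permutations, Gaussian regression at
n = 62); the suite-level false-positive rate pools slope terms across
replicate null model-suite runs.  The end-to-end check runs the full
chain at the study's shape (62 species, 24 scenarios, 36 cover species
× 30 sites).  Ties in the largest-remainder allocation break by group
order; zero-SE site slopes are floored at 10⁻⁸ before precision
weighting; rank-deficient designs and single-class Bernoulli responses
raise typed errors that the suite converts to named manifest skips.

## Known limitations

* The Bernoulli backend's walker-wise R̂ is conservative; borderline
  values near 1.05 can occur on small, weakly identified fits.
* Two-stage cover estimation discards cross-site shrinkage a full
  hierarchical model would provide; with very few sites per species the
  pooled intervals can be optimistic.
* The gains/losses subset transform re-estimates the shift constant on
  the subset, so slopes are not comparable across subsets on the
  transformed scale.
* Taxonomic standardisation is an input mapping applied verbatim; no
  nomenclature service is queried, and no unit conversion is attempted.
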