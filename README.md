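# shrubrange

Trait-based analysis of tundra shrub range dynamics: do species' trait
values and their intraspecific trait variation predict which shrubs win
and which lose under climate change?

`shrubrange` is a tested, reusable implementation of the analysis chain
linking individual trait measurements to range outcomes:

* **Trait pipeline** — TRY/Tundra-Trait-Team-style quality control of
  individual records for plant height (m), specific leaf area
  (SLA, mm²/mg) and seed mass (mg): provenance and latitude filters,
  duplicate removal, single-pass 4-SD outlier trimming, a ≥5-records
  rule, genus-level seed-mass gap-filling, and per-species summaries

  - MTV = ln(median of raw values) — the species' trait value,
  - ITV = ln(sample SD of raw values) — its intraspecific variation,

  each carrying a confidence index in [0.5, 1]
  (0.5 at five records, `0.33 + N/30` between 6 and 20, 1 above 20)
  used as a likelihood weight downstream.
* **Range processing** — log/centring transforms of current range sizes
  and of species-by-scenario ensembles of projected absolute (km²) and
  relative (%) range change, with ensemble quantiles (25/50/75%).
* **Classification** — future winners (ensemble 25% quantile > 0),
  losers (75% quantile < 0) and no-change species; past winners and
  losers from cover-change slopes whose 95% intervals exclude zero;
  cross-horizon agreement tables and functional-group compositions.
* **Cover change** — two-stage estimation of per-species cover trends
  from plot-level monitoring counts (Poisson GLM per species-by-site
  with subsite intercepts, then precision-weighted pooling).
* **Inference** — weighted Bayesian regressions (exact conjugate
  Gaussian backend; ensemble-MCMC Bernoulli backend robust to
  separation) with the credible-interval decision rule: an effect is a
  "clear relationship" when its 95% interval excludes zero.
  `run_model_suite` executes the full study catalogue (univariate,
  additive and interaction MTV/ITV models, categorical predictors,
  gains/losses subsets, cover-slope and winner-vs-rest models).
* **Multivariate** — PCA of trait space, PERMANOVA on Euclidean
  distances with a permutation null, distance-to-centroid dispersion
  homogeneity, and pairwise comparisons with Holm/Bonferroni adjustment.
* **Synthetic data** — generators for all four input kinds with known
  ground truth and flagged planted contaminants, so every stage is
  testable without external data.

## Worked example

```python
import shrubrange as sr

# a study-shaped synthetic dataset: 62 species, ~18k trait records
cfg = sr.TraitGeneratorConfig(species_count=62, records_per_species=96, seed=7)
records = sr.generate_trait_records(cfg)
summaries, logs = sr.run_trait_pipeline(records)
wide = sr.summaries_to_wide(summaries)

# a 24-scenario range-shift ensemble with a planted seed-mass-ITV effect
ensemble, truth = sr.generate_range_ensemble(
    sr.RangeGeneratorConfig(seed=8, intercept=-0.15,
                            trait_effect={"itv_seed_mass": 0.5}),
    wide,
)
res = sr.run_full_analysis(records, ensemble, permutations=999, random_state=9)
print(sr.category_shares(res.categories_future))
```

prints

```
            n   pct
category
winner     12  19.4
no_change  26  41.9
loser      24  38.7
```

— the winner/no-change/loser partition of the 62 species from the raw
ensemble quantiles (counts and percentages of the species pool).  The
fitted suite recovers the planted trait signal: the regression of the
transformed median absolute range shift on seed-mass ITV reports

```
abs_q50_t ~ itv_seed_mass: mean=0.229 CI=(0.212, 0.246) clear=True
```

(a clear positive relationship on the transformed modelling scale), and
because the categories were generated from that same trait, the
ITV-space PERMANOVA separates the groups decisively:

```
ITV PERMANOVA: F=26.777, p=0.001 (999 permutations)
ITV PC variance fractions: [0.413 0.309 0.278]
```

With `trait_effect={}` (the null default) the suite's clear-relationship
rate falls to the ~5% expected by chance — the multiplicity caveat of a
large uncorrected model catalogue.

A CLI mirrors the library: `shrubrange simulate|traits|classify|regress|ordinate`
(see `shrubrange --help`; CSV column meanings in
`docs/data_dictionary.md`).

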