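# Data dictionary

Column meanings for the CSV tables read and written by the library and
CLI.  All trait values are in native units (height m, SLA mm²/mg, seed
mass mg); MTV/ITV are natural logs of the median / sample SD of raw
values.

## trait_records.csv (input to `traits`; output of `simulate`)

| column | meaning |
| --- | --- |
| species | standardised species name |
| genus | genus (used for seed-mass gap-filling) |
| trait | `height`, `sla` or `seed_mass` |
| value | raw measurement, native unit, > 0 |
| latitude, longitude | decimal degrees; empty when not georeferenced |
| georeferenced | boolean |
| high_latitude_source | non-georeferenced record from a whitelisted high-latitude database |
| experimental | treatment/manipulated record (removed by the filter) |
| herbarium | herbarium specimen (removed by the filter) |
| source_id | source database identifier |
| collector | collector / dataset label (part of the duplicate key) |
| is_planted_outlier / is_planted_duplicate / is_planted_south | synthetic-data bookkeeping flags; ignored by the pipeline |

## trait_summaries.csv

species, trait, n_records, mtv, itv (empty when the group SD is 0),
gap_filled, index (confidence weight in [0.5, 1]).
`trait_summaries_wide.csv` pivots to one row per species with columns
`mtv_<trait>`, `itv_<trait>`, `index_<trait>`, `index_combined`.

## rejection_log.csv

The dropped trait-record rows plus `reason`: `malformed`,
`experimental`, `herbarium`, `south_of_30N`, or
`not_georeferenced_no_high_latitude_source`.

## range_ensemble.csv

| column | meaning |
| --- | --- |
| species | species name |
| current_range_km2 | projected current range size, km² |
| abs_change_sNN | absolute range change (km²) under scenario NN |
| rel_change_sNN | relative range change (%) under scenario NN |

## cover_series.csv

species, site, subsite, plot, year (integer index), cover (non-negative
integer cover score).

## cover_slopes.csv

species, slope_per_year (log-scale cover change per year), ci_low,
ci_high (95% interval), n_sites.

## categorical_traits.csv

species, family, dispersal_mode (`wind`/`animal_berry`), deciduousness
(`deciduous`/`evergreen`), max_canopy_height_cm, functional_group
(`dwarf`/`low`/`tall`).

## categories.csv / agreement.csv

categories.csv: species, horizon (`future`/`past`), category
(`winner`/`no_change`/`loser`) and the evidence that produced it
(q25/q50/q75 for future; slope/ci_low/ci_high for past).
agreement.csv: 3×3 future-by-past table over the shared species.

## fit_results.csv / manifest.csv

fit_results.csv: model (label), family, n, backend
(`conjugate`/`emcee`), converged, term, mean, ci_low, ci_high,
clear_relationship (95% interval excludes zero), rhat (empty for the
closed-form backend).
manifest.csv: label, family, status (`ok`/`skipped`), reason, n.

## ground_truth.csv / range_ground_truth.csv / cover_ground_truth.csv

Realised generator parameters: per species × trait log_median and
log_spread; per-species expected range change (10⁶ km²) and current
range; per-species cover trend per year.
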