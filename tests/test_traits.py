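"""Trait cleaning rules, summaries and confidence weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import shrubrange as sr
from shrubrange.traits import TraitPipelineError
from conftest import make_records


class TestFilterRecords:
    def test_georeferenced_south_of_30N_rejected(self):
        records = make_records([{"latitude": 25.0}])
        kept, log = sr.filter_records(records)
        assert kept.empty
        assert list(log["reason"]) == ["south_of_30N"]

    def test_nongeoreferenced_high_latitude_source_retained(self):
        records = make_records([{
            "georeferenced": False, "latitude": np.nan, "longitude": np.nan,
            "high_latitude_source": True, "experimental": False,
        }])
        kept, log = sr.filter_records(records)
        assert len(kept) == 1 and log.empty

    def test_experimental_and_herbarium_removed(self):
        records = make_records([
            {"experimental": True}, {"herbarium": True}, {},
        ])
        kept, log = sr.filter_records(records)
        assert len(kept) == 1
        assert sorted(log["reason"]) == ["experimental", "herbarium"]

    def test_malformed_value_logged_not_fatal(self):
        records = make_records([{"value": -3.0}, {"value": np.nan}])
        kept, log = sr.filter_records(records)
        assert kept.empty
        assert list(log["reason"].unique()) == ["malformed"]

    def test_empty_input_gives_empty_output_and_log(self):
        records = make_records([]).iloc[:0]
        kept, log = sr.filter_records(records)
        assert kept.empty and log.empty


class TestDeduplicate:
    def test_identical_rows_collapse(self):
        records = make_records([{"value": 2.0}, {"value": 2.0}])
        kept, n = sr.deduplicate(records)
        assert len(kept) == 1 and n == 1

    def test_same_value_different_coordinates_both_kept(self):
        records = make_records([{"value": 2.0, "latitude": 60.0},
                                {"value": 2.0, "latitude": 61.0}])
        kept, n = sr.deduplicate(records)
        assert len(kept) == 2 and n == 0

    def test_planted_duplicates_all_removed(self):
        cfg = sr.TraitGeneratorConfig(
            species_count=2, records_per_species=50, duplicate_fraction=0.1,
            outlier_fraction=0.0, south_fraction=0.0, nongeoref_fraction=0.0, seed=8,
        )
        records = sr.generate_trait_records(cfg)
        n_planted = int(records["is_planted_duplicate"].sum())
        kept, n_removed = sr.deduplicate(records)
        assert n_planted > 0 and n_removed == n_planted


class TestTrimOutliers:
    def test_weak_in_tiny_groups(self):
        # {1,1,1,1,100}: mean 20.8, sample SD 44.27, |100-20.8| < 4 SD -> kept
        records = make_records([{"value": v} for v in [1, 1, 1, 1, 100]])
        assert len(sr.trim_outliers(records)) == 5

    def test_planted_seven_sd_outlier_removed(self):
        rng = np.random.default_rng(0)
        values = list(rng.normal(10, 1, size=1000)) + [17.0]
        records = make_records([{"value": v} for v in values])
        kept = sr.trim_outliers(records)
        # brute-force recomputation of the rule
        v = np.asarray(values)
        expect_drop = np.abs(v - v.mean()) > 4 * v.std(ddof=1)
        assert expect_drop.sum() == 1 and 17.0 not in kept["value"].to_numpy()
        assert len(kept) == 1000

    def test_identical_values_untouched(self):
        records = make_records([{"value": 3.0}] * 6)
        assert len(sr.trim_outliers(records)) == 6


class TestMinRecordsAndSummaries:
    def test_four_records_dropped_five_retained(self):
        records = make_records(
            [{"species": "a", "value": v} for v in (1, 2, 3, 4)]
            + [{"species": "b", "value": v} for v in (1, 2, 3, 4, 5)]
        )
        kept, dropped = sr.apply_min_records(records)
        assert set(kept["species"]) == {"b"}
        assert dropped.iloc[0]["n_records"] == 4

    def test_summary_of_one_to_five(self):
        records = make_records([{"value": v} for v in (1, 2, 3, 4, 5)])
        out = sr.summarise(records)
        assert out.iloc[0]["mtv"] == pytest.approx(np.log(3), abs=1e-12)
        assert out.iloc[0]["itv"] == pytest.approx(np.log(np.sqrt(2.5)), abs=1e-9)
        assert out.iloc[0]["itv"] == pytest.approx(0.4581, abs=1e-4)

    def test_zero_sd_gives_missing_itv(self):
        records = make_records([{"value": 1.0}] * 5)
        out = sr.summarise(records)
        assert out.iloc[0]["mtv"] == 0.0
        assert np.isnan(out.iloc[0]["itv"])

    @settings(derandomize=True, max_examples=30)
    @given(
        values=st.lists(st.floats(0.1, 100.0), min_size=5, max_size=20),
        c=st.floats(0.01, 50.0),
    )
    def test_scale_equivariance(self, values, c):
        """Multiplying raw values by c adds exactly ln(c) to MTV and ITV."""
        base = sr.summarise(make_records([{"value": v} for v in values]))
        scaled = sr.summarise(make_records([{"value": v * c} for v in values]))
        assert scaled.iloc[0]["mtv"] == pytest.approx(base.iloc[0]["mtv"] + np.log(c), abs=1e-8)
        if np.isfinite(base.iloc[0]["itv"]):
            assert scaled.iloc[0]["itv"] == pytest.approx(base.iloc[0]["itv"] + np.log(c), abs=1e-6)


class TestGapFill:
    def _pool(self, values, lat=65.0, genus="gen_x"):
        return make_records([
            {"species": f"donor_{i}", "genus": genus, "trait": "seed_mass",
             "value": v, "latitude": lat}
            for i, v in enumerate(values)
        ])

    def test_pool_of_four_stays_unfilled(self):
        records = self._pool([1, 2, 3, 4])
        filled, unfilled = sr.gap_fill_seed_mass(records, ["target"], {"target": "gen_x"})
        assert filled.empty and len(unfilled) == 1

    def test_constant_pool_of_five(self):
        records = self._pool([2, 2, 2, 2, 2])
        filled, _ = sr.gap_fill_seed_mass(records, ["target"], {"target": "gen_x"})
        row = filled.iloc[0]
        assert row["mtv"] == pytest.approx(np.log(2), abs=1e-12)
        assert np.isnan(row["itv"]) and row["index"] == 0.5 and row["gap_filled"]

    def test_low_latitude_pool_excluded(self):
        records = self._pool([2, 2, 2, 2, 2], lat=55.0)  # below 60N
        filled, unfilled = sr.gap_fill_seed_mass(records, ["target"], {"target": "gen_x"})
        assert filled.empty and len(unfilled) == 1

    def test_species_with_own_seed_mass_untouched_by_pipeline(self):
        cfg = sr.TraitGeneratorConfig(species_count=2, records_per_species=30, seed=3,
                                      outlier_fraction=0, duplicate_fraction=0,
                                      south_fraction=0, nongeoref_fraction=0)
        records = sr.generate_trait_records(cfg)
        summaries, _ = sr.run_trait_pipeline(records, gap_fill=True)
        seed_rows = summaries[summaries["trait"] == "seed_mass"]
        assert not seed_rows["gap_filled"].any()


class TestConfidenceIndex:
    @pytest.mark.parametrize("n,expected", [
        (5, 0.5), (25, 1.0), (6, 0.53), (15, 0.83), (21, 1.0), (20, 0.33 + 20 / 30),
    ])
    def test_piecewise_rule(self, n, expected):
        assert sr.confidence_index(n) == pytest.approx(expected, abs=1e-9)

    def test_gap_filled_is_half(self):
        assert sr.confidence_index(0, gap_filled=True) == 0.5

    def test_below_five_records_is_contract_violation(self):
        with pytest.raises(TraitPipelineError):
            sr.confidence_index(4)

    def test_monotone_and_bounded(self):
        vals = [sr.confidence_index(n) for n in range(5, 40)]
        assert all(0.5 <= v <= 1.0 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("indices,expected", [
        ([1, 0.5, 0.5], 2 / 3), ([1], 1.0), ([0.53, 0.83, 1], 0.7867),
    ])
    def test_combined_index_mean(self, indices, expected):
        assert sr.combined_index(indices) == pytest.approx(expected, abs=1e-4)

    def test_combined_index_requires_input(self):
        with pytest.raises(TraitPipelineError):
            sr.combined_index([])


class TestFunctionalGroup:
    @pytest.mark.parametrize("h,expected", [
        (19.9, "dwarf"), (20, "low"), (50, "low"), (51, "tall"),
    ])
    def test_height_classes(self, h, expected):
        assert sr.assign_functional_group(h) == expected

    def test_nonpositive_height_rejected(self):
        with pytest.raises(TraitPipelineError):
            sr.assign_functional_group(0)


def test_cleaning_removes_exactly_planted_contaminants():
    """In a regime where the clean trait law has no mass near the 4-SD
    envelope (small log-spread), the cleaning chain removes exactly the
    planted outliers/duplicates/southern rows and nothing else."""
    cfg = sr.TraitGeneratorConfig(
        species_count=5, records_per_species=60, log_spread=0.1,
        species_median_sd=0.0, species_spread_sigma=0.0,
        outlier_fraction=0.02, duplicate_fraction=0.05, south_fraction=0.03,
        nongeoref_fraction=0.1, seed=21,
    )
    records = sr.generate_trait_records(cfg)
    planted = records[["is_planted_outlier", "is_planted_duplicate", "is_planted_south"]].any(axis=1)
    kept, log = sr.filter_records(records)
    kept, n_dup = sr.deduplicate(kept)
    kept = sr.trim_outliers(kept)
    clean_ids = set(records.index[~planted])
    kept_ids = set(kept.index)
    assert kept_ids == clean_ids  # exactly the planted rows removed, nothing else
    assert n_dup == int(records["is_planted_duplicate"].sum())
    assert (log["reason"] == "south_of_30N").sum() == int(records["is_planted_south"].sum())


def test_trim_agrees_with_brute_force_oracle_at_realistic_spread():
    """At realistic (heavy-tailed) trait spreads some genuine records fall
    beyond 4 SD; the trim must remove precisely the rows a brute-force
    recomputation of the rule flags — planted outliers always included."""
    cfg = sr.TraitGeneratorConfig(
        species_count=5, records_per_species=60, outlier_fraction=0.02,
        duplicate_fraction=0.0, south_fraction=0.0, nongeoref_fraction=0.0, seed=21,
    )
    records = sr.generate_trait_records(cfg)
    kept = sr.trim_outliers(records)
    removed = set(records.index) - set(kept.index)
    expected = set()
    for _, grp in records.groupby(["species", "trait"]):
        v = grp["value"].to_numpy()
        mask = np.abs(v - v.mean()) > 4 * v.std(ddof=1)
        expected |= set(grp.index[mask])
    assert removed == expected
    assert set(records.index[records["is_planted_outlier"]]) <= removed
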