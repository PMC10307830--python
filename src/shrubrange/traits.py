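"""Trait-record cleaning and per-species trait summaries.

Raw inputs are individual trait measurements (one row per individual) for
three size/economics traits of tundra shrubs: plant height (m), specific
leaf area (SLA, mm^2/mg) and seed mass (mg).  The pipeline mirrors a
TRY/Tundra-Trait-Team style quality-control protocol:

1. geographic / provenance filtering (keep georeferenced records above
   30 degrees N, plus non-georeferenced records from whitelisted
   high-latitude sources; drop experimental treatments and herbarium
   specimens),
2. duplicate removal,
3. single-pass 4-standard-deviation outlier trimming within each
   species-by-trait group,
4. a minimum of five records per species-by-trait combination,

after which each retained group is summarised by its median trait value
(MTV, stored as the natural log of the median raw value) and its
intraspecific trait variation (ITV, the natural log of the sample SD of
raw values).  Species without seed-mass data can be gap-filled from
genus-level records above 60 degrees N.  Every species-by-trait summary
carries a confidence index in [0.5, 1] that downstream regressions use
as a likelihood weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAITS = ("height", "sla", "seed_mass")

#: columns that identify a duplicated measurement.  The source database is
#: deliberately not part of the key: the same measurement deposited in two
#: databases is a duplicate.
DEDUP_KEY = ["species", "trait", "value", "latitude", "longitude", "collector"]

RECORD_COLUMNS = [
    "species", "genus", "trait", "value", "latitude", "longitude",
    "georeferenced", "high_latitude_source", "experimental", "herbarium",
    "source_id", "collector",
]


class TraitPipelineError(ValueError):
    """Contract violation in the trait pipeline."""


def _as_float(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def filter_records(records: pd.DataFrame, min_latitude: float = 30.0):
    """Apply the provenance and geography filters.

    Retains rows that are (georeferenced with latitude strictly above
    ``min_latitude`` degrees N) or (non-georeferenced but from a
    whitelisted high-latitude source), and that are neither experimental
    treatments nor herbarium specimens.

    Returns ``(retained, rejection_log)``; the log carries every dropped
    row plus a ``reason`` column.  Malformed rows (non-positive or
    missing trait values, impossible coordinates) are never fatal: they
    go to the log with reason ``"malformed"``.
    """
    if records.empty:
        empty = records.copy()
        log = records.copy()
        log["reason"] = pd.Series(dtype=object)
        return empty, log

    df = records.copy()
    value = _as_float(df["value"])
    lat = _as_float(df["latitude"]) if "latitude" in df else pd.Series(np.nan, index=df.index)
    georef = df["georeferenced"].fillna(False).astype(bool)
    high_lat = df["high_latitude_source"].fillna(False).astype(bool)
    experimental = df["experimental"].fillna(False).astype(bool)
    herbarium = df["herbarium"].fillna(False).astype(bool)

    reason = pd.Series("", index=df.index, dtype=object)

    malformed = ~(value > 0) | (georef & (lat.isna() | (lat.abs() > 90)))
    reason[malformed] = "malformed"

    ok = ~malformed
    reason[ok & experimental] = "experimental"
    ok &= ~experimental
    reason[ok & herbarium] = "herbarium"
    ok &= ~herbarium

    south = ok & georef & (lat <= min_latitude)
    reason[south] = "south_of_30N"
    no_provenance = ok & ~georef & ~high_lat
    reason[no_provenance] = "not_georeferenced_no_high_latitude_source"
    ok &= ~(south | no_provenance)

    retained = df[ok].copy()
    log = df[~ok].copy()
    log["reason"] = reason[~ok]
    return retained, log


def deduplicate(records: pd.DataFrame, key: list[str] | None = None):
    """Collapse rows identical on the duplicate key to a single row.

    Missing coordinates compare equal to missing coordinates, so two
    non-georeferenced copies of the same measurement still collapse.
    Returns ``(retained, n_removed)``.
    """
    if records.empty:
        return records.copy(), 0
    key = key or [c for c in DEDUP_KEY if c in records.columns]
    dup = records.duplicated(subset=key, keep="first")
    return records[~dup].copy(), int(dup.sum())


def trim_outliers(records: pd.DataFrame, n_sd: float = 4.0) -> pd.DataFrame:
    """Single-pass outlier trim within each species-by-trait group.

    A row is dropped when its raw value lies more than ``n_sd`` sample
    standard deviations from its group mean, with mean and SD computed
    once on the untrimmed group (not iterated).  Groups of size one, or
    with zero SD, are kept untouched.
    """
    if records.empty:
        return records.copy()
    grp = records.groupby(["species", "trait"])["value"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1; NaN for singleton groups
    dist = (records["value"] - mean).abs()
    drop = sd.notna() & (sd > 0) & (dist > n_sd * sd)
    return records[~drop].copy()


def apply_min_records(records: pd.DataFrame, min_records: int = 5):
    """Drop species-by-trait groups with fewer than ``min_records`` rows.

    Returns ``(retained, dropped_log)`` where the log lists each dropped
    group with its record count.
    """
    if records.empty:
        log = pd.DataFrame(columns=["species", "trait", "n_records"])
        return records.copy(), log
    counts = records.groupby(["species", "trait"])["value"].transform("size")
    keep = counts >= min_records
    dropped = (
        records[~keep]
        .groupby(["species", "trait"])
        .size()
        .rename("n_records")
        .reset_index()
    )
    return records[keep].copy(), dropped


def confidence_index(n_records: int, gap_filled: bool = False) -> float:
    """Confidence index in [0.5, 1] for a species-by-trait summary.

    Gap-filled summaries and those built from exactly five records get
    0.5; more than 20 records gets 1; in between the index interpolates
    linearly as ``0.33 + n/30``.  ``n_records = 20`` falls on the linear
    rule (0.9967), which joins the two endpoints continuously.
    """
    if gap_filled:
        return 0.5
    n = int(n_records)
    if n < 5:
        raise TraitPipelineError(
            f"confidence_index requires at least 5 records (got {n}) unless gap-filled"
        )
    if n == 5:
        return 0.5
    if n > 20:
        return 1.0
    return 0.33 + n / 30.0


def combined_index(indices) -> float:
    """Arithmetic mean of the available per-trait confidence indices."""
    vals = [float(v) for v in indices if v is not None and np.isfinite(v)]
    if not vals:
        raise TraitPipelineError("combined_index requires at least one per-trait index")
    return float(np.mean(vals))


def summarise(records: pd.DataFrame, min_records: int = 5) -> pd.DataFrame:
    """Per species-by-trait summaries of the cleaned records.

    MTV is the natural log of the median raw value; ITV the natural log
    of the sample (n-1) SD.  A group whose SD is exactly zero has its
    ITV recorded as missing (NaN) rather than -inf.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["species", "trait", "n_records", "mtv", "itv", "gap_filled", "index"]
        )
    rows = []
    for (species, trait), grp in records.groupby(["species", "trait"], sort=True):
        v = grp["value"].to_numpy(dtype=float)
        if v.size < min_records:
            raise TraitPipelineError(
                f"summarise requires >= {min_records} records per group; "
                f"{species}/{trait} has {v.size} (run apply_min_records first)"
            )
        sd = float(np.std(v, ddof=1))
        rows.append({
            "species": species,
            "trait": trait,
            "n_records": int(v.size),
            "mtv": float(np.log(np.median(v))),
            "itv": float(np.log(sd)) if sd > 0 else np.nan,
            "gap_filled": False,
            "index": confidence_index(v.size),
        })
    return pd.DataFrame(rows)


def gap_fill_seed_mass(
    records: pd.DataFrame,
    target_species,
    genus_map: dict[str, str] | None = None,
    min_records: int = 5,
    min_latitude: float = 60.0,
):
    """Genus-level seed-mass summaries for species lacking their own.

    For each target species, seed-mass records of its genus that are
    georeferenced above ``min_latitude`` degrees N are pooled; when the
    pool holds at least ``min_records`` values a summary row is emitted
    with the genus-level MTV/ITV, ``gap_filled=True`` and confidence
    index 0.5.  Returns ``(summaries, unfilled_log)``.
    """
    genus_map = genus_map or (
        records.drop_duplicates("species").set_index("species")["genus"].to_dict()
    )
    seed = records[records["trait"] == "seed_mass"]
    lat = _as_float(seed["latitude"]) if len(seed) else pd.Series(dtype=float)
    pool_all = seed[(seed["georeferenced"].astype(bool)) & (lat > min_latitude)] if len(seed) else seed

    rows, unfilled = [], []
    for sp in target_species:
        genus = genus_map.get(sp)
        if genus is None:
            unfilled.append({"species": sp, "reason": "genus_unknown"})
            continue
        pool = pool_all[pool_all["genus"] == genus]["value"].to_numpy(dtype=float)
        if pool.size < min_records:
            unfilled.append({"species": sp, "reason": f"genus_pool_n={pool.size}"})
            continue
        sd = float(np.std(pool, ddof=1))
        rows.append({
            "species": sp,
            "trait": "seed_mass",
            "n_records": int(pool.size),
            "mtv": float(np.log(np.median(pool))),
            "itv": float(np.log(sd)) if sd > 0 else np.nan,
            "gap_filled": True,
            "index": 0.5,
        })
    cols = ["species", "trait", "n_records", "mtv", "itv", "gap_filled", "index"]
    return (
        pd.DataFrame(rows, columns=cols),
        pd.DataFrame(unfilled, columns=["species", "reason"]),
    )


def assign_functional_group(max_canopy_height_cm: float) -> str:
    """Shrub functional group from maximum canopy height.

    dwarf (< 20 cm), low (20-50 cm inclusive), tall (> 50 cm).
    """
    h = float(max_canopy_height_cm)
    if not h > 0:
        raise TraitPipelineError(f"max canopy height must be positive (got {h})")
    if h < 20:
        return "dwarf"
    if h <= 50:
        return "low"
    return "tall"


def run_trait_pipeline(
    records: pd.DataFrame,
    min_records: int = 5,
    outlier_sd: float = 4.0,
    gap_fill: bool = True,
    synonym_map: dict[str, str] | None = None,
):
    """filter -> deduplicate -> trim -> min-records -> summarise (+ gap fill).

    ``synonym_map`` is an optional species-synonym -> accepted-name table
    applied verbatim before any filtering.  Returns ``(summaries, logs)``
    where ``logs`` is a dict of the per-stage rejection tables.
    """
    df = records.copy()
    if synonym_map:
        df["species"] = df["species"].replace(synonym_map)
    retained, rejection_log = filter_records(df)
    retained, n_dup = deduplicate(retained)
    retained = trim_outliers(retained, n_sd=outlier_sd)
    retained, min_log = apply_min_records(retained, min_records=min_records)
    summaries = summarise(retained, min_records=min_records)

    logs = {"rejected": rejection_log, "duplicates_removed": n_dup, "too_few_records": min_log}
    if gap_fill and not summaries.empty:
        have_seed = set(summaries.loc[summaries["trait"] == "seed_mass", "species"])
        by_sp = summaries.groupby("species")["trait"].apply(set)
        targets = sorted(
            sp for sp, tr in by_sp.items()
            if sp not in have_seed and {"height", "sla"} <= tr
        )
        filled, unfilled = gap_fill_seed_mass(retained, targets, min_records=min_records)
        if not filled.empty:
            summaries = pd.concat([summaries, filled], ignore_index=True)
        logs["gap_fill_unfilled"] = unfilled
    return summaries.sort_values(["species", "trait"]).reset_index(drop=True), logs


def summaries_to_wide(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pivot long summaries to one row per species.

    Columns are ``mtv_<trait>``, ``itv_<trait>``, ``index_<trait>``,
    plus ``index_combined`` (mean of the available per-trait indices).
    """
    wide = summaries.pivot(index="species", columns="trait")
    out = pd.DataFrame(index=wide.index)
    for field, prefix in [("mtv", "mtv"), ("itv", "itv"), ("index", "index")]:
        if field in summaries.columns:
            for trait in summaries["trait"].unique():
                if (field, trait) in wide.columns:
                    out[f"{prefix}_{trait}"] = wide[(field, trait)]
    idx_cols = [c for c in out.columns if c.startswith("index_")]
    out["index_combined"] = out[idx_cols].mean(axis=1, skipna=True)
    return out
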