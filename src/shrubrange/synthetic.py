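"""Synthetic trait, range-ensemble, cover and categorical-trait data.

Every downstream stage of the package is testable against known ground
truth through these generators.  Defaults emulate the shape of the
study system: 62 shrub species, three traits with roughly 17,900
records in total, a 24-member ensemble of projected range shifts, and
ITEX-style cover monitoring across 30 sites.

Trait values are lognormal — species' trait differences live on a log
scale, so exp(Normal(log_median, log_spread)) is the minimal law whose
log-median and log-SD are the generator's own parameters.  Planted
contaminants (outliers beyond the 4-SD trim envelope, exact duplicate
rows, records south of 30 degrees N) are flagged in ``is_planted_*``
columns so tests can verify the cleaning stage removes exactly them.

Counts of planted rows use floor-plus-largest-remainder rounding of
fraction x n so they are reproducible and sum to round(fraction x total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .traits import TRAITS, assign_functional_group

FAMILIES = (
    "Betulaceae", "Salicaceae", "Ericaceae", "Rosaceae",
    "Caprifoliaceae", "Myricaceae", "Cornaceae", "Grossulariaceae",
)

#: minimum planted-outlier offset, in clean-group SDs above the mean.  The
#: actual offset is raised deterministically until the planted value lies
#: beyond the 4-SD envelope of the *contaminated* group, so the trim rule
#: removes every planted outlier regardless of the outlier fraction.
OUTLIER_OFFSET_SD = 6.0
_TRIM_MARGIN_SD = 4.3  # target distance in contaminated-group SDs (> the 4-SD rule)

DEFAULT_LOG_MEDIAN = {"height": np.log(0.4), "sla": np.log(12.0), "seed_mass": np.log(1.5)}
DEFAULT_LOG_SPREAD = {"height": 0.6, "sla": 0.4, "seed_mass": 0.7}
#: between-species SD of the species-level log-medians (species genuinely
#: differ; trait differences live on the log scale)
DEFAULT_SPECIES_MEDIAN_SD = {"height": 0.8, "sla": 0.5, "seed_mass": 1.0}


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class MissingTraitError(KeyError):
    """A species lacks a trait summary the range generator needs."""


def largest_remainder_counts(group_sizes: np.ndarray, fraction: float) -> np.ndarray:
    """Allocate round(fraction * total) planted rows across groups.

    Quotas fraction*n_g are floored, then the remaining units go to the
    groups with the largest fractional remainders (ties broken by group
    order).  Deterministic and sums exactly to round(fraction * total).
    """
    n = np.asarray(group_sizes, dtype=float)
    total = int(np.floor(fraction * n.sum() + 0.5))
    quota = fraction * n
    counts = np.floor(quota).astype(int)
    short = total - int(counts.sum())
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _plant_outlier_value(clean_values: np.ndarray, k: int) -> float:
    """Smallest offset >= 6 clean-SDs whose k planted copies still exceed
    the 4-SD trim envelope of the contaminated group."""
    m, s = clean_values.mean(), clean_values.std(ddof=1)
    if s == 0:
        s = max(abs(m), 1.0) * 0.1
    for c in np.arange(OUTLIER_OFFSET_SD, 200.0, 0.5):
        value = m + c * s
        contaminated = np.concatenate([clean_values, np.full(k, value)])
        sd_c = contaminated.std(ddof=1)
        if abs(value - contaminated.mean()) > _TRIM_MARGIN_SD * sd_c:
            return float(value)
    return float(m + 200.0 * s)


def _species_names(k: int) -> list[str]:
    return [f"species_{i + 1:02d}" for i in range(k)]


def _resolve_grid(param, species: Sequence[str], traits: Sequence[str], name: str) -> pd.DataFrame:
    """Broadcast a scalar / per-trait dict / DataFrame to species x trait."""
    if isinstance(param, pd.DataFrame):
        return param.loc[list(species), list(traits)].astype(float)
    if isinstance(param, Mapping):
        row = {t: float(param[t]) for t in traits}
        return pd.DataFrame({t: row[t] for t in traits}, index=list(species))
    return pd.DataFrame(float(param), index=list(species), columns=list(traits))


@dataclass
class TraitGeneratorConfig:
    """Configuration of the individual-trait-record generator.

    ``log_median`` / ``log_spread`` may be a scalar, a per-trait mapping
    or a species x trait DataFrame, in natural-log units of each trait's
    native unit (m, mm^2/mg, mg); they give the biome-level centre of
    each trait.  On top of that, species-level log-medians are offset by
    Normal(0, ``species_median_sd``) and log-spreads multiplied by
    exp(Normal(0, ``species_spread_sigma``)), seeded, so species differ
    the way real species do (set both to 0 to pin every species to the
    stated values).  Fractions are relative to the clean base record
    count; contaminants are appended as extra rows.
    """

    species_count: int = 62
    records_per_species: int | Mapping[str, int] = 96  # per species x trait
    log_median: object = field(default_factory=lambda: dict(DEFAULT_LOG_MEDIAN))
    log_spread: object = field(default_factory=lambda: dict(DEFAULT_LOG_SPREAD))
    species_median_sd: object = field(default_factory=lambda: dict(DEFAULT_SPECIES_MEDIAN_SD))
    species_spread_sigma: float = 0.3
    outlier_fraction: float = 0.01
    duplicate_fraction: float = 0.007
    nongeoref_fraction: float = 0.10
    south_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.species_count < 1:
            raise ConfigurationError("species_count must be >= 1")
        for name in ("outlier_fraction", "duplicate_fraction", "nongeoref_fraction", "south_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")

    @property
    def species(self) -> list[str]:
        return _species_names(self.species_count)

    def records_for(self, species: str) -> int:
        n = self.records_per_species[species] if isinstance(self.records_per_species, Mapping) \
            else self.records_per_species
        if n < 1:
            raise ConfigurationError("records_per_species must be >= 1")
        return int(n)

    def ground_truth(self, traits: Sequence[str] = TRAITS) -> pd.DataFrame:
        """Realised true log-median and log-spread per species x trait.

        Species-level offsets are drawn from a dedicated seeded stream,
        so the same config always describes the same ground truth.
        """
        sp = self.species
        med = _resolve_grid(self.log_median, sp, traits, "log_median").copy()
        spread = _resolve_grid(self.log_spread, sp, traits, "log_spread").copy()
        med_sd = _resolve_grid(self.species_median_sd, sp, traits, "species_median_sd")
        if (med_sd.to_numpy() < 0).any():
            raise ConfigurationError("species_median_sd must be non-negative")
        if self.species_spread_sigma < 0:
            raise ConfigurationError("species_spread_sigma must be non-negative")
        rng = np.random.default_rng([int(self.seed), 101])
        for t in traits:
            med[t] = med[t] + rng.normal(0.0, 1.0, len(sp)) * med_sd[t]
            spread[t] = spread[t] * np.exp(rng.normal(0.0, self.species_spread_sigma, len(sp)))
        if (spread.to_numpy() <= 0).any():
            raise ConfigurationError("log_spread must be positive")
        rows = [
            {"species": s, "trait": t,
             "log_median": med.loc[s, t], "log_spread": spread.loc[s, t]}
            for s in sp for t in traits
        ]
        return pd.DataFrame(rows)


def generate_trait_records(cfg: TraitGeneratorConfig, traits: Sequence[str] = TRAITS) -> pd.DataFrame:
    """Individual trait records with flagged planted contaminants.

    Clean base records are georeferenced at 45-75 degrees N (a fraction
    ``nongeoref_fraction`` of them made non-georeferenced but flagged as
    coming from a high-latitude source, so the cleaning stage retains
    them).  Contaminants — +6-SD outliers, exact duplicates of clean
    rows, and records south of 30 degrees N — are appended and flagged
    in ``is_planted_outlier`` / ``is_planted_duplicate`` /
    ``is_planted_south``.  Output is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = cfg.ground_truth(traits).set_index(["species", "trait"])
    species = cfg.species
    genus = {s: f"genus_{(i // 2) + 1:02d}" for i, s in enumerate(species)}

    frames = []
    group_sizes = []
    for s in species:
        n = cfg.records_for(s)
        for t in traits:
            mu = float(truth.loc[(s, t), "log_median"])
            sig = float(truth.loc[(s, t), "log_spread"])
            values = np.exp(rng.normal(mu, sig, size=n))
            lat = rng.uniform(45.0, 75.0, size=n)
            lon = rng.uniform(-160.0, 60.0, size=n)
            df = pd.DataFrame({
                "species": s, "genus": genus[s], "trait": t, "value": values,
                "latitude": lat, "longitude": lon,
                "georeferenced": True, "high_latitude_source": False,
                "experimental": False, "herbarium": False,
                "source_id": "synthetic_db", "collector": f"collector_{s}",
                "is_planted_outlier": False, "is_planted_duplicate": False,
                "is_planted_south": False,
            })
            frames.append(df)
            group_sizes.append(n)
    records = pd.concat(frames, ignore_index=True)
    sizes = np.asarray(group_sizes)
    groups = [(s, t) for s in species for t in traits]

    # non-georeferenced high-latitude records (retained, not contaminants)
    for (s, t), k in zip(groups, largest_remainder_counts(sizes, cfg.nongeoref_fraction)):
        if k == 0:
            continue
        idx = records.index[(records["species"] == s) & (records["trait"] == t)][:k]
        records.loc[idx, ["latitude", "longitude"]] = np.nan
        records.loc[idx, "georeferenced"] = False
        records.loc[idx, "high_latitude_source"] = True

    extras = []
    # planted outliers: at least mean + 6 SD of the clean group, raised
    # deterministically until they sit beyond the 4-SD envelope of the
    # contaminated group, so the trim rule removes exactly them
    for (s, t), k in zip(groups, largest_remainder_counts(sizes, cfg.outlier_fraction)):
        if k == 0:
            continue
        grp = records[(records["species"] == s) & (records["trait"] == t)]
        v = grp["value"].to_numpy()
        outlier_value = _plant_outlier_value(v, k)
        for j in range(k):
            extras.append({
                "species": s, "genus": genus[s], "trait": t,
                "value": outlier_value * (1 + 1e-6 * j),  # distinct, same envelope
                "latitude": rng.uniform(45.0, 75.0), "longitude": rng.uniform(-160.0, 60.0),
                "georeferenced": True, "high_latitude_source": False,
                "experimental": False, "herbarium": False,
                "source_id": "synthetic_db", "collector": f"collector_{s}",
                "is_planted_outlier": True, "is_planted_duplicate": False,
                "is_planted_south": False,
            })
    # planted duplicates: exact copies of clean georeferenced rows
    for (s, t), k in zip(groups, largest_remainder_counts(sizes, cfg.duplicate_fraction)):
        if k == 0:
            continue
        grp = records[
            (records["species"] == s) & (records["trait"] == t) & records["georeferenced"]
        ]
        pick = grp.iloc[rng.choice(len(grp), size=min(k, len(grp)), replace=False)]
        for _, row in pick.iterrows():
            dup = row.to_dict()
            dup["is_planted_duplicate"] = True
            extras.append(dup)
    # planted south-of-30N records
    for (s, t), k in zip(groups, largest_remainder_counts(sizes, cfg.south_fraction)):
        mu = float(truth.loc[(s, t), "log_median"])
        sig = float(truth.loc[(s, t), "log_spread"])
        for _ in range(k):
            extras.append({
                "species": s, "genus": genus[s], "trait": t,
                "value": float(np.exp(rng.normal(mu, sig))),
                "latitude": rng.uniform(0.0, 29.9), "longitude": rng.uniform(-160.0, 60.0),
                "georeferenced": True, "high_latitude_source": False,
                "experimental": False, "herbarium": False,
                "source_id": "synthetic_db", "collector": f"collector_{s}",
                "is_planted_outlier": False, "is_planted_duplicate": False,
                "is_planted_south": True,
            })
    if extras:
        records = pd.concat([records, pd.DataFrame(extras)], ignore_index=True)
    return records.sort_values(
        ["species", "trait", "is_planted_outlier", "is_planted_duplicate", "is_planted_south"],
        kind="stable",
    ).reset_index(drop=True)


def generate_categorical_traits(species: Sequence[str], seed: int = 0) -> pd.DataFrame:
    """Categorical trait table: family, dispersal mode, deciduousness,
    maximum canopy height (cm) and the functional group it implies."""
    rng = np.random.default_rng(seed)
    height_cm = np.exp(rng.normal(np.log(40.0), 0.9, size=len(species)))
    return pd.DataFrame({
        "species": list(species),
        "family": rng.choice(FAMILIES, size=len(species)),
        "dispersal_mode": rng.choice(["wind", "animal_berry"], size=len(species)),
        "deciduousness": rng.choice(["deciduous", "evergreen"], size=len(species), p=[0.6, 0.4]),
        "max_canopy_height_cm": height_cm,
        "functional_group": [assign_functional_group(h) for h in height_cm],
    })


@dataclass
class RangeGeneratorConfig:
    """Configuration of the scenario range-shift ensemble generator.

    ``trait_effect`` maps trait-summary column names (e.g.
    ``"itv_seed_mass"``) to ground-truth slopes in million km^2 of
    absolute range change per unit of the (log-scale) trait summary.
    ``scenario_noise_sd`` is the across-scenario spread, also in
    million km^2; the study found strong differences between its 24
    climatic scenarios, hence a noise SD of the same order as the mean
    shift.
    """

    scenario_count: int = 24
    trait_effect: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0  # million km^2; null default: no mean shift
    scenario_noise_sd: float = 0.5  # million km^2
    current_range_log_mean: float = np.log(5e6)
    current_range_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario_count < 2:
            raise ConfigurationError("scenario_count must be >= 2")
        if not self.scenario_noise_sd > 0:
            raise ConfigurationError("scenario_noise_sd must be positive")


def generate_range_ensemble(cfg: RangeGeneratorConfig, summaries_wide: pd.DataFrame):
    """Species x scenario range-change ensemble from trait summaries.

    ``summaries_wide`` is indexed by species with trait-summary columns
    (see :func:`shrubrange.traits.summaries_to_wide`).  Absolute change
    for species i in scenario s is
    ``1e6 * (intercept + sum_j beta_j * x_ij + eps_is)`` km^2 with
    eps ~ Normal(0, scenario_noise_sd); relative change is absolute /
    current range x 100.  Returns ``(ensemble, truth)`` where truth
    stores each species' expected change (million km^2) and the effects
    used.
    """
    rng = np.random.default_rng(cfg.seed)
    species = list(summaries_wide.index)
    mu = np.full(len(species), cfg.intercept, dtype=float)
    for col, beta in cfg.trait_effect.items():
        if col not in summaries_wide.columns:
            raise MissingTraitError(f"trait summary column {col!r} not present")
        x = summaries_wide[col].to_numpy(dtype=float)
        missing = summaries_wide.index[~np.isfinite(x)].tolist()
        if missing:
            raise MissingTraitError(f"missing {col!r} for species: {missing}")
        mu = mu + float(beta) * x

    current = np.exp(rng.normal(cfg.current_range_log_mean, cfg.current_range_log_sd, len(species)))
    eps = rng.normal(0.0, cfg.scenario_noise_sd, size=(len(species), cfg.scenario_count))
    abs_change = 1e6 * (mu[:, None] + eps)
    rel_change = abs_change / current[:, None] * 100.0

    ensemble = pd.DataFrame({"species": species, "current_range_km2": current})
    for s in range(cfg.scenario_count):
        ensemble[f"abs_change_s{s + 1:02d}"] = abs_change[:, s]
    for s in range(cfg.scenario_count):
        ensemble[f"rel_change_s{s + 1:02d}"] = rel_change[:, s]
    truth = pd.DataFrame({
        "species": species,
        "expected_change_mkm2": mu,
        "current_range_km2": current,
    })
    return ensemble, truth


@dataclass
class CoverGeneratorConfig:
    """Configuration of the plot-level cover time-series generator.

    ``species_trend`` maps species names to log-scale cover change per
    year.  Cover counts are Poisson with log-rate
    ``intercept + site effect + subsite effect + trend * (year - mid)``.
    """

    species_trend: Mapping[str, float] = field(default_factory=lambda: {"species_01": 0.0})
    site_count: int = 30
    subsite_per_site: int = 4
    plot_per_subsite: int = 3
    year_count: int = 20
    intercept: float = np.log(5.0)
    site_intercept_sd: float = 0.3
    subsite_intercept_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.year_count < 3:
            raise ConfigurationError("year_count must be >= 3")
        for name in ("site_count", "subsite_per_site", "plot_per_subsite"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.site_intercept_sd < 0 or self.subsite_intercept_sd < 0:
            raise ConfigurationError("random-intercept SDs must be non-negative")


def generate_cover_series(cfg: CoverGeneratorConfig):
    """Plot-level Poisson cover counts with site/subsite structure.

    Returns ``(observations, truth)``; truth records each species' true
    trend.  Years are indexed 0..year_count-1 and the trend applies to
    the centred year, matching the estimator's parameterisation.
    """
    rng = np.random.default_rng(cfg.seed)
    years = np.arange(cfg.year_count)
    year_c = years - years.mean()
    rows = []
    for species in sorted(cfg.species_trend):
        trend = float(cfg.species_trend[species])
        for si in range(cfg.site_count):
            site_eff = rng.normal(0.0, cfg.site_intercept_sd) if cfg.site_intercept_sd > 0 else 0.0
            for bi in range(cfg.subsite_per_site):
                sub_eff = rng.normal(0.0, cfg.subsite_intercept_sd) if cfg.subsite_intercept_sd > 0 else 0.0
                log_rate = cfg.intercept + site_eff + sub_eff + trend * year_c
                for pi in range(cfg.plot_per_subsite):
                    cover = rng.poisson(np.exp(log_rate))
                    rows.append(pd.DataFrame({
                        "species": species,
                        "site": f"site_{si + 1:02d}",
                        "subsite": f"site_{si + 1:02d}_sub_{bi + 1:02d}",
                        "plot": f"site_{si + 1:02d}_sub_{bi + 1:02d}_plot_{pi + 1:02d}",
                        "year": years,
                        "cover": cover,
                    }))
    observations = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {"species": sorted(cfg.species_trend),
         "trend_per_year": [cfg.species_trend[s] for s in sorted(cfg.species_trend)]}
    )
    return observations, truth
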