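"""Per-species cover-change slopes from plot-level monitoring series.

Cover scores are ordinal counts recorded per plot and year in a nested
site/subsite design (ITEX-style monitoring).  Estimation is two-stage:

1. within each species-by-site combination, a Poisson log-linear GLM of
   cover on (centred) year with subsite-level intercepts gives a slope
   (log-scale cover change per year) and its standard error;
2. site slopes are pooled per species by precision weighting, giving a
   species-level slope and a 95% interval of the pooled estimator.

Two-stage pooling is unbiased for the slope under the generative model
(Poisson counts with site/subsite intercept offsets and a common
species trend) and keeps the estimator fast and deterministic; a full
hierarchical sampler can be swapped in behind the same output contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

MIN_YEARS = 3


def fit_site_slopes(observations: pd.DataFrame, min_years: int = MIN_YEARS):
    """Poisson GLM slope of cover on year per species-by-site.

    Subsites enter as intercept dummies when a site has more than one.
    Species-by-site combinations with fewer than ``min_years`` distinct
    years, all-zero cover, or a failed fit are skipped and logged.

    Returns ``(slopes, skipped)``: slopes has columns species, site,
    slope, se, n_obs, n_subsites; skipped has species, site, reason.
    """
    rows, skipped = [], []
    for (species, site), grp in observations.groupby(["species", "site"], sort=True):
        years = grp["year"].nunique()
        if years < min_years:
            skipped.append({"species": species, "site": site, "reason": "too_few_years"})
            continue
        y = grp["cover"].to_numpy(dtype=float)
        if not np.any(y > 0):
            skipped.append({"species": species, "site": site, "reason": "all_zero_cover"})
            continue
        year_c = grp["year"].to_numpy(dtype=float)
        year_c = year_c - year_c.mean()
        X = pd.DataFrame({"intercept": 1.0, "year": year_c}, index=grp.index)
        if grp["subsite"].nunique() > 1:
            dummies = pd.get_dummies(grp["subsite"], prefix="subsite", drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        try:
            fit = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson()).fit()
            slope = float(fit.params[1])
            se = float(fit.bse[1])
            if not (np.isfinite(slope) and np.isfinite(se) and se > 0):
                raise ValueError("degenerate fit")
        except Exception:
            skipped.append({"species": species, "site": site, "reason": "fit_failed"})
            continue
        rows.append({
            "species": species, "site": site, "slope": slope, "se": se,
            "n_obs": int(len(grp)), "n_subsites": int(grp["subsite"].nunique()),
        })
    return (
        pd.DataFrame(rows, columns=["species", "site", "slope", "se", "n_obs", "n_subsites"]),
        pd.DataFrame(skipped, columns=["species", "site", "reason"]),
    )


def aggregate_species_slopes(site_slopes: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Precision-weighted pooling of site slopes to the species level.

    The species slope is the inverse-variance weighted mean of its site
    slopes; the interval is the normal interval of that pooled mean.
    A single site passes through unchanged (slope and interval from its
    own standard error).
    """
    z = stats.norm.ppf(0.5 + ci_level / 2)
    rows = []
    for species, grp in site_slopes.groupby("species", sort=True):
        se = np.maximum(grp["se"].to_numpy(dtype=float), 1e-8)
        w = 1.0 / se**2
        slope = float(np.sum(w * grp["slope"].to_numpy()) / np.sum(w))
        se_pooled = float(np.sqrt(1.0 / np.sum(w)))
        rows.append({
            "species": species,
            "slope_per_year": slope,
            "ci_low": slope - z * se_pooled,
            "ci_high": slope + z * se_pooled,
            "n_sites": int(len(grp)),
        })
    return pd.DataFrame(rows, columns=["species", "slope_per_year", "ci_low", "ci_high", "n_sites"])


def estimate_cover_slopes(observations: pd.DataFrame, min_years: int = MIN_YEARS):
    """Full two-stage estimate: site GLMs then precision-weighted pooling.

    Returns ``(species_slopes, skipped)``.
    """
    site_slopes, skipped = fit_site_slopes(observations, min_years=min_years)
    if site_slopes.empty:
        empty = pd.DataFrame(columns=["species", "slope_per_year", "ci_low", "ci_high", "n_sites"])
        return empty, skipped
    return aggregate_species_slopes(site_slopes), skipped
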