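"""Winner / no-change / loser classification and category tabulations.

Future categories come from the raw-scale ensemble quantiles of
projected range shifts: a species is a future winner when the 25%
quantile of its shift distribution is strictly above zero, a future
loser when the 75% quantile is strictly below zero, and no-change
otherwise (a quantile exactly at zero reads as overlapping zero).
Past categories come from per-species cover-change slopes: winner when
the 95% interval lies strictly above zero, loser when strictly below.

Because relative change is a positive per-species rescaling of absolute
change, the two yield identical categories — the agreement the
cross-tabulation quantifies between horizons is therefore about the
future-vs-past comparison, not the absolute-vs-relative one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = ("winner", "no_change", "loser")


def classify_future(q25: float, q50: float, q75: float) -> str:
    """Category from the (25%, 50%, 75%) ensemble quantiles of range shift."""
    if not (q25 <= q50 <= q75):
        raise ValueError(f"quantiles must be ordered, got ({q25}, {q50}, {q75})")
    if q25 > 0:
        return "winner"
    if q75 < 0:
        return "loser"
    return "no_change"


def classify_past(slope: float, ci_low: float, ci_high: float) -> str:
    """Category from a cover-change slope and its 95% interval."""
    if not (ci_low <= slope <= ci_high):
        raise ValueError(
            f"interval must contain the slope, got slope={slope}, CI=({ci_low}, {ci_high})"
        )
    if ci_low > 0:
        return "winner"
    if ci_high < 0:
        return "loser"
    return "no_change"


def classify_future_table(quantile_summary: pd.DataFrame, kind: str = "abs") -> pd.DataFrame:
    """Classify every species from a raw-scale quantile summary table.

    ``quantile_summary`` is indexed by species with columns
    ``<kind>_q25/q50/q75`` (see :func:`shrubrange.ranges.summarise_ensemble`).
    """
    cols = [f"{kind}_q25", f"{kind}_q50", f"{kind}_q75"]
    rows = []
    for sp, r in quantile_summary[cols].iterrows():
        rows.append({
            "species": sp,
            "horizon": "future",
            "category": classify_future(*r.to_numpy(dtype=float)),
            "q25": r[cols[0]], "q50": r[cols[1]], "q75": r[cols[2]],
        })
    return pd.DataFrame(rows)


def classify_past_table(cover_slopes: pd.DataFrame) -> pd.DataFrame:
    """Classify every species from slope/ci_low/ci_high columns."""
    rows = []
    for _, r in cover_slopes.iterrows():
        rows.append({
            "species": r["species"],
            "horizon": "past",
            "category": classify_past(r["slope_per_year"], r["ci_low"], r["ci_high"]),
            "slope": r["slope_per_year"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
        })
    return pd.DataFrame(rows)


def cross_tabulate(future: pd.DataFrame, past: pd.DataFrame):
    """3x3 future-by-past agreement table over the shared species.

    Returns ``(table, shared_count)`` where the shared count is the
    trace of the table (species with the same category on both horizons).
    """
    f = future.set_index("species")["category"]
    p = past.set_index("species")["category"]
    common = f.index.intersection(p.index)
    if len(common) == 0:
        raise ValueError("future and past classifications share no species")
    table = pd.crosstab(f.loc[common], p.loc[common])
    table = table.reindex(index=CATEGORIES, columns=CATEGORIES, fill_value=0)
    table.index.name, table.columns.name = "future", "past"
    shared = int(np.trace(table.to_numpy()))
    return table, shared


def category_shares(categories: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentage of all species per category.

    Percentages are rounded to one decimal for reporting; raw counts are
    retained.
    """
    counts = categories["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame({
        "n": counts.astype(int),
        "pct": (counts / total * 100).round(1),
    })


def category_composition(categories: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Functional-group composition within each category.

    ``groups`` maps species to a group label.  Percentages are computed
    within category and rounded to one decimal; raw counts retained.
    Raises if any classified species lacks a group label.
    """
    cats = categories.set_index("species")["category"]
    missing = cats.index.difference(groups.index).tolist()
    if missing:
        raise ValueError(f"missing group label for species: {missing}")
    df = pd.DataFrame({"category": cats, "group": groups.loc[cats.index]})
    counts = df.groupby(["category", "group"]).size().rename("n").reset_index()
    totals = counts.groupby("category")["n"].transform("sum")
    counts["pct"] = (counts["n"] / totals * 100).round(1)
    return counts
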