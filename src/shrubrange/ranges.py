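"""Transforms of current range sizes and ensemble range-shift matrices.

Current range sizes (km^2) are log-transformed and centred.  Projected
range shifts come as a species-by-scenario matrix of absolute (km^2) and
relative (%) change; because shifts can be negative, the modelling
transform first scales them (absolute by 1e6 km^2, relative by 100),
adds a dataset-level constant c = -min(scaled) + 1 so everything is
positive, takes natural logs, and centres.  The constant and the
transformed image of zero raw change (the winner/loser boundary) are
carried through so results can be read back on the original scale.

Classification itself operates on raw-scale ensemble quantiles; the
transform exists for the regression stage only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

QUANTILE_PROBS = (0.25, 0.5, 0.75)

ABS_SCALE = 1e6   # km^2 divisor for absolute range change
REL_SCALE = 100.0  # divisor for relative (%) range change


@dataclass
class ShiftTransform:
    """A log-shift-centred range-shift variable and its bookkeeping.

    ``zero_reference`` is the transformed-scale image of zero raw
    change: ln(shift_constant) - centring_mean.
    """

    values: pd.Series
    kind: str
    shift_constant: float
    centring_mean: float
    zero_reference: float
    scale: float = field(default=ABS_SCALE)


def transform_current_range(current_range_km2: pd.Series) -> pd.Series:
    """Natural-log transform and centre current range sizes (km^2)."""
    v = pd.Series(current_range_km2, dtype=float)
    bad = v.index[~(v > 0)].tolist()
    if bad:
        raise ValueError(f"non-positive current range size for species: {bad}")
    logv = np.log(v)
    return logv - logv.mean()


def transform_range_shift(values: pd.Series, kind: str) -> ShiftTransform:
    """Scale, shift-to-positive, log and centre a range-shift vector.

    ``kind`` is ``"absolute"`` (km^2, divided by 1e6) or ``"relative"``
    (%, divided by 100).
    """
    if kind not in ("absolute", "relative"):
        raise ValueError(f"kind must be 'absolute' or 'relative', got {kind!r}")
    v = pd.Series(values, dtype=float)
    if v.empty:
        raise ValueError("transform_range_shift requires a non-empty vector")
    scale = ABS_SCALE if kind == "absolute" else REL_SCALE
    scaled = v / scale
    c = -float(scaled.min()) + 1.0
    logged = np.log(scaled + c)
    mean = float(logged.mean())
    return ShiftTransform(
        values=logged - mean,
        kind=kind,
        shift_constant=c,
        centring_mean=mean,
        zero_reference=float(np.log(c) - mean),
        scale=scale,
    )


def ensemble_quantiles(values, probs=QUANTILE_PROBS) -> np.ndarray:
    """Quantiles of one species' shift distribution across scenarios.

    Uses linear interpolation of order statistics (the conventional
    default estimator), pinned because quantiles of a 24-point sample
    differ across estimators.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"ensemble quantiles require >= 2 scenarios, got {v.size}")
    return np.quantile(v, probs, method="linear")


def summarise_ensemble(ensemble: pd.DataFrame, probs=QUANTILE_PROBS) -> pd.DataFrame:
    """Raw-scale per-species ensemble quantiles.

    ``ensemble`` has one row per species with columns ``abs_change_*``
    and ``rel_change_*`` (one per scenario) plus ``current_range_km2``.
    Returns one row per species with ``abs_q25 ... rel_q75`` and the
    current range carried through.
    """
    abs_cols = [c for c in ensemble.columns if c.startswith("abs_change_")]
    rel_cols = [c for c in ensemble.columns if c.startswith("rel_change_")]
    if len(abs_cols) < 2 and len(rel_cols) < 2:
        raise ValueError("ensemble table must contain >= 2 abs_change_/rel_change_ scenario columns")
    out = pd.DataFrame({"species": ensemble["species"]})
    labels = [f"q{int(round(p * 100))}" for p in probs]
    for kind, cols in (("abs", abs_cols), ("rel", rel_cols)):
        if not cols:
            continue
        q = np.quantile(ensemble[cols].to_numpy(dtype=float), probs, axis=1)
        for lab, row in zip(labels, q):
            out[f"{kind}_{lab}"] = row
    if "current_range_km2" in ensemble.columns:
        out["current_range_km2"] = ensemble["current_range_km2"].to_numpy()
    return out.set_index("species")


def transformed_responses(quantile_summary: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regression-scale response variables from raw quantile summaries.

    Each quantile column is transformed as its own dataset-level
    variable (its own shift constant and centring mean).  Returns
    ``(responses, constants)`` where responses has columns
    ``<col>_t`` plus ``log_centred_current_range``, and constants
    records the shift constant, centring mean and zero reference per
    transformed column.
    """
    out = pd.DataFrame(index=quantile_summary.index)
    consts = []
    for col in quantile_summary.columns:
        if col.startswith("abs_") or col.startswith("rel_"):
            kind = "absolute" if col.startswith("abs_") else "relative"
            tr = transform_range_shift(quantile_summary[col], kind)
            out[f"{col}_t"] = tr.values
            consts.append({
                "column": f"{col}_t",
                "kind": kind,
                "shift_constant": tr.shift_constant,
                "centring_mean": tr.centring_mean,
                "zero_reference": tr.zero_reference,
            })
    if "current_range_km2" in quantile_summary.columns:
        out["log_centred_current_range"] = transform_current_range(
            quantile_summary["current_range_km2"]
        )
    return out, pd.DataFrame(consts)
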