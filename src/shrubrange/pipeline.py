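"""End-to-end orchestration: records -> summaries -> categories -> models.

Glue over the module pipeline for one-call analyses and for the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import classify as classmod
from . import cover as covermod
from . import inference, multivariate
from . import ranges as rangemod
from . import traits as traitmod


@dataclass
class AnalysisResult:
    summaries: pd.DataFrame
    summaries_wide: pd.DataFrame
    quantiles: pd.DataFrame
    categories_future: pd.DataFrame
    categories_past: pd.DataFrame | None
    cover_slopes: pd.DataFrame | None
    fits: list
    manifest: pd.DataFrame
    ordinations: dict
    permanova: dict
    logs: dict = field(default_factory=dict)


def run_full_analysis(
    trait_records: pd.DataFrame,
    ensemble: pd.DataFrame,
    cover_observations: pd.DataFrame | None = None,
    categorical_traits: pd.DataFrame | None = None,
    min_records: int = 5,
    outlier_sd: float = 4.0,
    gap_fill: bool = True,
    permutations: int = 999,
    random_state: int = 0,
    logistic_kwargs: dict | None = None,
) -> AnalysisResult:
    """Run the whole analysis chain on raw inputs.

    Cleans and summarises trait records, classifies future winners and
    losers from raw ensemble quantiles (and past ones from cover slopes
    when monitoring data are given), runs the full regression suite, and
    ordinates the complete-trait species with PERMANOVA group tests.
    """
    summaries, logs = traitmod.run_trait_pipeline(
        trait_records, min_records=min_records, outlier_sd=outlier_sd, gap_fill=gap_fill
    )
    wide = traitmod.summaries_to_wide(summaries)

    quant = rangemod.summarise_ensemble(ensemble)
    categories_future = classmod.classify_future_table(quant, kind="abs")

    cover_slopes = categories_past = None
    if cover_observations is not None:
        cover_slopes, skipped = covermod.estimate_cover_slopes(cover_observations)
        logs["cover_skipped"] = skipped
        if not cover_slopes.empty:
            categories_past = classmod.classify_past_table(cover_slopes)

    fits, manifest = inference.run_model_suite(
        wide, ensemble,
        categories_future=categories_future,
        cover_slopes=cover_slopes,
        categorical_traits=categorical_traits,
        categories_past=categories_past,
        random_state=random_state,
        logistic_kwargs=logistic_kwargs,
    )

    ordinations, perma = {}, {}
    cat = categories_future.set_index("species")["category"]
    for metric in ("mtv", "itv"):
        cols = [f"{metric}_{t}" for t in traitmod.TRAITS]
        have = [c for c in cols if c in wide.columns]
        matrix = wide[have].dropna()
        if len(matrix) >= 3 and len(have) == len(cols):
            try:
                ord_res = multivariate.pca(matrix)
            except ValueError:
                continue
            ordinations[metric] = ord_res
            labels = cat.reindex(matrix.index).dropna()
            aligned = matrix.loc[labels.index]
            if labels.nunique() >= 2 and labels.value_counts().min() >= 2:
                perma[metric] = multivariate.permanova(
                    aligned, labels, permutations=permutations, seed=random_state
                )
    return AnalysisResult(
        summaries=summaries, summaries_wide=wide, quantiles=quant,
        categories_future=categories_future, categories_past=categories_past,
        cover_slopes=cover_slopes, fits=fits, manifest=manifest,
        ordinations=ordinations, permanova=perma, logs=logs,
    )
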