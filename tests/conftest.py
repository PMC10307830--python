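import numpy as np
import pandas as pd
import pytest

import shrubrange as sr


def make_records(rows):
    """Build a trait-record table from partial row dicts with sane defaults."""
    defaults = {
        "species": "sp_a", "genus": "gen_a", "trait": "height", "value": 1.0,
        "latitude": 65.0, "longitude": 20.0, "georeferenced": True,
        "high_latitude_source": False, "experimental": False, "herbarium": False,
        "source_id": "db1", "collector": "c1",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture(scope="session")
def small_trait_data():
    """Cleaned synthetic trait dataset shared by pipeline-level tests."""
    cfg = sr.TraitGeneratorConfig(species_count=12, records_per_species=40, seed=101)
    records = sr.generate_trait_records(cfg)
    summaries, logs = sr.run_trait_pipeline(records)
    wide = sr.summaries_to_wide(summaries)
    return {"cfg": cfg, "records": records, "summaries": summaries, "wide": wide, "logs": logs}


@pytest.fixture(scope="session")
def null_ensemble(small_trait_data):
    cfg = sr.RangeGeneratorConfig(seed=7)
    ensemble, truth = sr.generate_range_ensemble(cfg, small_trait_data["wide"])
    return ensemble, truth
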