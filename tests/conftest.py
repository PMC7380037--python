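import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trophodiet.io import make_taxonomy_row
from trophodiet.table import MotuTable

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


def build_table(counts: dict, taxonomy: dict, samples: dict) -> MotuTable:
    """Assemble a MotuTable from plain dicts.

    counts: {motu_id: {sample_id: n}}; taxonomy: {motu_id: kwargs for
    make_taxonomy_row}; samples: {sample_id: metadata dict}.
    """
    sample_ids = list(samples)
    cdf = pd.DataFrame(
        {s: {m: counts[m].get(s, 0) for m in counts} for s in sample_ids}
    ).astype(np.int64)
    cdf = cdf.loc[list(counts)]
    tdf = pd.DataFrame(
        {m: make_taxonomy_row(**kw) for m, kw in taxonomy.items()}
    ).T
    defaults = {"sample_type": "stomach", "site": "A", "estuary": "E1",
                "country": "XX", "pool_size": 8}
    sdf = pd.DataFrame(
        {s: {**defaults, **kw} for s, kw in samples.items()}
    ).T
    sdf.loc[sdf["sample_type"] != "stomach", "pool_size"] = pd.NA
    return MotuTable(cdf, tdf, sdf)


@pytest.fixture
def small_table() -> MotuTable:
    """3 MOTUs x 4 samples: two stomachs, one sediment, one control."""
    return build_table(
        counts={
            "m1": {"st1": 50, "st2": 30, "sed1": 10, "nc1": 0},
            "m2": {"st1": 50, "st2": 0, "sed1": 80, "nc1": 0},
            "m3": {"st1": 0, "st2": 70, "sed1": 10, "nc1": 2},
        },
        taxonomy={
            "m1": dict(rank="species", kingdom="Eukaryota", phylum="Arthropoda",
                       genus="Carcinus", species="Carcinus maenas"),
            "m2": dict(rank="species", kingdom="Eukaryota", phylum="Annelida",
                       genus="Hediste", species="Hediste diversicolor"),
            "m3": dict(rank="genus", kingdom="Eukaryota", phylum="Arthropoda",
                       genus="Crangon"),
        },
        samples={
            "st1": dict(sample_type="stomach", site="A"),
            "st2": dict(sample_type="stomach", site="A"),
            "sed1": dict(sample_type="sediment", site="A"),
            "nc1": dict(sample_type="negative_control", site=pd.NA,
                        estuary=pd.NA),
        },
    )
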