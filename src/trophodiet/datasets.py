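"""Bundled reference data.

``load_reference_diet_table`` returns the published diet-summary table
for adult brown shrimp (Crangon crangon) across six European estuaries:
the 21 taxa that reached ≥0.5% mean relative read abundance in stomach
samples, with their printed presence (%), mean (±SE) relative abundance
(%), mean (±SE) Jacobs' selectivity index and trophic-significance
category.  It is the worked-example input for the trophic-significance
arithmetic and the reporting-rule checks; it is real published output,
not synthetic data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_REFERENCE_FILE = "published_diet_table.tsv"


def load_reference_diet_table() -> pd.DataFrame:
    """The published C. crangon diet summary (21 rows, printed precision).

    Columns: phylum, order, family, species, rank, best_identity,
    presence_pct, mean_abundance_pct, se_abundance_pct, jacobs_D, se_D,
    category.  Percentages are on the printed 0–100 scale.
    """
    ref = resources.files("trophodiet.data").joinpath(_REFERENCE_FILE)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df


def count_reported_species(
    table: pd.DataFrame, min_abundance_pct: float = 0.5
) -> int:
    """Apply the reporting rule: species-rank taxa at ≥ the abundance cutoff.

    Counts rows assigned at species rank whose mean relative abundance
    reaches ``min_abundance_pct`` (printed percent scale) — the number
    of ascertained prey species a diet table reports.
    """
    ok = (table["rank"] == "species") & (
        table["mean_abundance_pct"] >= min_abundance_pct
    )
    return int(ok.sum())
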