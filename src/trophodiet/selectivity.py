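"""Prey selectivity and trophic significance from paired diet/eDNA tables.

The central contrast is between what a consumer ate (relative read
abundance r of a taxon in a stomach sample) and what was available
(relative abundance p of the same taxon in the sediment eDNA sample of
the same site).  Jacobs' selectivity index

    D = (r - p) / (r + p - 2 r p)

maps that contrast onto [-1, 1]: -1 total avoidance, 0 neutral (passive)
intake in proportion to availability, +1 exclusive selection.  Unlike
the raw ratio r/p it corrects for prey depletion and is antisymmetric in
(r, p).

Each taxon is then ranked by a composite trophic-significance score

    TS = a * f * (D + 1)      in [0, 2],

where a is the mean relative diet abundance over all retained stomach
samples (zeros included), f the fraction of stomach samples containing
the taxon, and D its mean Jacobs index over informative stomach/sediment
pairs.  Scores are reported as shares of the total (relative TS) and
binned High (>10%), Medium (1-10%), Low (<1%) — taxon-level read
abundances in metabarcoding are semi-quantitative, so categories are
more defensible than exact values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .table import RANKS, MotuTable, ValidationError


class SelectivityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary statistics


def jacobs_index(r, p):
    """Jacobs' selectivity index D = (r - p) / (r + p - 2 r p).

    ``r`` is the taxon's relative abundance in the diet, ``p`` in the
    environment; both in [0, 1].  Scalar or array-valued.  The index is
    undefined (NaN) when r = p = 0 or r = p = 1 (zero denominator);
    callers decide how to treat such pairs.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((r < 0) | (r > 1) | (p < 0) | (p > 1)):
        raise SelectivityError("r and p must lie in [0,1]")
    denom = r + p - 2.0 * r * p
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom == 0, np.nan, (r - p) / np.where(denom == 0, 1, denom))
    # guard floating-point overshoot at the extremes (e.g. r=1 gives
    # (1-p)/(1-p) which can round to 1 + 1ulp)
    d = np.clip(d, -1.0, 1.0)
    if d.ndim == 0:
        return float(d)
    return d


def trophic_significance(a, f, d):
    """TS = a * f * (D + 1); monotone non-decreasing in each argument."""
    a = np.asarray(a, dtype=float)
    f = np.asarray(f, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((f < 0) | (f > 1)):
        raise SelectivityError("a and f must lie in [0,1]")
    if np.any((d < -1) | (d > 1)):
        raise SelectivityError("D must lie in [-1,1]")
    ts = a * f * (d + 1.0)
    if ts.ndim == 0:
        return float(ts)
    return ts


def presence_fraction(table: MotuTable, motu_id: str, sample_group: Sequence[str]) -> float:
    """Fraction of the given samples in which the MOTU has any reads."""
    group = list(sample_group)
    if not group:
        raise SelectivityError("empty sample group")
    row = table.counts.loc[motu_id, group]
    return float((row > 0).sum() / len(group))


def relative_abundance(table: MotuTable, sample_id: str) -> pd.Series:
    """Per-MOTU read fraction within one sample (sums to 1)."""
    return table.relative_abundance(sample_id)


# ---------------------------------------------------------------------------
# pairing


@dataclass(frozen=True)
class SitePairing:
    """Map from each stomach sample to the sediment sample of its site."""

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", dict(self.pairs))

    def __iter__(self):
        return iter(self.pairs.items())

    def __len__(self) -> int:
        return len(self.pairs)

    def sediment_for(self, stomach_id: str) -> str:
        return self.pairs[stomach_id]


def pair_by_site(diet_table: MotuTable, env_table: MotuTable) -> SitePairing:
    """Pair every stomach sample with its site's single sediment sample.

    Raises when a stomach sample's site has no (or more than one)
    sediment sample — the design collects one pooled sediment extract
    per site, so anything else signals a data problem.
    """
    diet_meta = diet_table.samples
    env_meta = env_table.samples
    stomach = diet_meta.index[diet_meta["sample_type"] == "stomach"]
    sediment = env_meta[env_meta["sample_type"] == "sediment"]
    by_site = sediment.groupby("site").groups
    pairs: dict[str, str] = {}
    for s in stomach:
        site = diet_meta.loc[s, "site"]
        if site not in by_site:
            raise SelectivityError(
                f"stomach sample {s!r} at site {site!r} has no sediment sample"
            )
        candidates = list(by_site[site])
        if len(candidates) != 1:
            raise SelectivityError(
                f"site {site!r} has {len(candidates)} sediment samples; expected 1"
            )
        pairs[s] = candidates[0]
    if not pairs:
        raise SelectivityError("no stomach samples to pair")
    return SitePairing(pairs)


# ---------------------------------------------------------------------------
# per-MOTU summaries


def _sem(values: np.ndarray) -> float:
    """Standard error of the mean (sample SD / sqrt(n)); 0 for n=1."""
    n = len(values)
    if n <= 1:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(n))


def paired_selectivity(
    diet_table: MotuTable,
    env_table: MotuTable,
    pairing: SitePairing,
) -> pd.DataFrame:
    """Mean (± SE) Jacobs' D per MOTU over stomach/sediment pairs.

    D is evaluated on every (stomach, paired sediment) pair from that
    pair's relative abundances; pairs where the MOTU is absent from both
    members (r = p = 0, index undefined) are excluded.  Returns a frame
    indexed by motu_id with columns ``jacobs_D``, ``se_D``, ``n_pairs``;
    a MOTU absent from every pair gets ``n_pairs = 0`` and NaN D,
    flagged rather than produced by NaN arithmetic.
    """
    motus = diet_table.motu_ids
    # r and p matrices: motu x pair
    r_cols, p_cols = [], []
    for stomach_id, sediment_id in pairing:
        r_cols.append(diet_table.relative_abundance(stomach_id))
        p = env_table.relative_abundance(sediment_id)
        p_cols.append(p.reindex(motus).fillna(0.0))
    r = np.column_stack([c.reindex(motus).fillna(0.0) for c in r_cols])
    p = np.column_stack(p_cols)
    d = jacobs_index(r, p)
    informative = (r + p) > 0
    rows = []
    for i, m in enumerate(motus):
        di = d[i, informative[i]]
        di = di[~np.isnan(di)]
        if len(di) == 0:
            rows.append({"motu_id": m, "jacobs_D": np.nan, "se_D": np.nan,
                         "n_pairs": 0})
        else:
            rows.append({
                "motu_id": m,
                "jacobs_D": float(np.mean(di)),
                "se_D": _sem(di),
                "n_pairs": int(len(di)),
            })
    return pd.DataFrame(rows).set_index("motu_id")


def categorize(
    records: pd.DataFrame,
    high: float = 0.10,
    low: float = 0.01,
    total_ts: float | None = None,
) -> pd.DataFrame:
    """Attach relative TS shares and High/Medium/Low categories.

    ``relative_TS = TS / total``; by default the denominator is the sum
    over the given records, or pass ``total_ts`` to normalise against a
    wider set (e.g. all MOTUs when records are the reported subset).
    High: share > ``high``; Low: share < ``low``; Medium: in between
    (inclusive of both bounds).
    """
    if "trophic_significance" not in records.columns:
        raise SelectivityError("records need a trophic_significance column")
    ts = records["trophic_significance"].astype(float)
    total = float(ts.sum()) if total_ts is None else float(total_ts)
    if total <= 0:
        raise SelectivityError("all trophic-significance scores are zero")
    out = records.copy()
    rel = ts / total
    out["relative_TS"] = rel
    out["category"] = np.select(
        [rel > high, rel < low], ["High", "Low"], default="Medium"
    )
    return out


def diet_summary(
    diet_table: MotuTable,
    env_table: MotuTable,
    pairing: SitePairing | None = None,
    report_threshold: float = 0.005,
    high: float = 0.10,
    low: float = 0.01,
    relative_ts_over_all: bool = True,
) -> pd.DataFrame:
    """Per-MOTU diet descriptor table (presence, abundance, D, TS, category).

    Mean relative abundance is averaged over *all* retained stomach
    samples, zeros included.  Only MOTUs whose mean relative abundance
    reaches ``report_threshold`` (default 0.5%) are reported; pass 0 to
    report everything.  When ``relative_ts_over_all`` is true (default)
    relative TS is normalised against the TS total of all MOTUs, not
    only the reported subset.  Rows are sorted by phylum then taxonomy.
    """
    if pairing is None:
        pairing = pair_by_site(diet_table, env_table)
    stomach_ids = [s for s, _ in pairing]
    missing = [s for s in diet_table.sample_ids
               if diet_table.samples.loc[s, "sample_type"] == "stomach"
               and s not in set(stomach_ids)]
    if missing:
        raise SelectivityError(f"pairing does not cover stomach samples {missing}")

    rel = np.column_stack(
        [diet_table.relative_abundance(s) for s in stomach_ids]
    )  # motu x stomach
    motus = diet_table.motu_ids
    n = len(stomach_ids)
    mean_a = rel.mean(axis=1)
    se_a = rel.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(motus))
    pres = (rel > 0).sum(axis=1) / n

    sel = paired_selectivity(diet_table, env_table, pairing)

    tax = diet_table.taxonomy
    df = pd.DataFrame(
        {
            "phylum": tax["phylum"].fillna("unassigned"),
            "order": tax["order"],
            "family": tax["family"],
            "species": tax["species"],
            "rank": tax["rank"],
            "best_identity": tax["best_identity"],
            "presence_fraction": pres,
            "mean_rel_abundance": mean_a,
            "se_rel_abundance": se_a,
        },
        index=motus,
    )
    df = df.join(sel)
    d_for_ts = df["jacobs_D"].fillna(0.0).clip(-1.0, 1.0)
    df["trophic_significance"] = trophic_significance(
        df["mean_rel_abundance"].to_numpy(),
        df["presence_fraction"].to_numpy(),
        d_for_ts.to_numpy(),
    )
    total_ts = float(df["trophic_significance"].sum())
    reported = df[df["mean_rel_abundance"] >= report_threshold]
    if reported.empty:
        raise SelectivityError("no MOTU passes the reporting threshold")
    reported = categorize(
        reported, high=high, low=low,
        total_ts=total_ts if relative_ts_over_all else None,
    )
    reported = reported.sort_values(
        ["phylum", "order", "family", "species"],
        na_position="last", kind="mergesort",
    )
    reported.index.name = "motu_id"
    return reported


def aggregate_to_phylum(table: MotuTable) -> MotuTable:
    """Sum counts to one row per phylum (missing phylum → 'unassigned')."""
    phyla = table.taxonomy["phylum"].fillna("unassigned")
    counts = table.counts.groupby(phyla).sum()
    tax = pd.DataFrame(
        {
            "rank": "phylum",
            "kingdom": pd.NA,
            "phylum": counts.index,
            "class": pd.NA, "order": pd.NA, "family": pd.NA,
            "genus": pd.NA, "species": pd.NA,
            "best_identity": np.nan,
        },
        index=counts.index,
    )
    tax.loc[tax["phylum"] == "unassigned", "rank"] = "unassigned"
    tax.loc[tax["phylum"] == "unassigned", "phylum"] = pd.NA
    return MotuTable(counts, tax, table.samples)


def phylum_summary(
    diet_table: MotuTable,
    env_table: MotuTable,
    pairing: SitePairing | None = None,
) -> pd.DataFrame:
    """Diet descriptors aggregated at phylum level (presence, abundance in
    diet and environment, Jacobs' D, TS) — the phylum-importance view."""
    if pairing is None:
        pairing = pair_by_site(diet_table, env_table)
    diet_ph = aggregate_to_phylum(diet_table)
    env_ph = aggregate_to_phylum(env_table)
    out = diet_summary(
        diet_ph, env_ph, pairing,
        report_threshold=0.0, relative_ts_over_all=True,
    )
    # add environment-side mean abundance per phylum
    sed_ids = sorted({sed for _, sed in pairing})
    env_rel = np.column_stack(
        [env_ph.relative_abundance(s) for s in sed_ids]
    )
    env_mean = pd.Series(env_rel.mean(axis=1), index=env_ph.motu_ids)
    out["mean_env_abundance"] = env_mean.reindex(out.index).fillna(0.0)
    keep = [
        "phylum", "presence_fraction", "mean_rel_abundance",
        "se_rel_abundance", "mean_env_abundance", "jacobs_D", "se_D",
        "n_pairs", "trophic_significance", "relative_TS", "category",
    ]
    return out[keep].sort_values("trophic_significance", ascending=False)


def format_percent(x: float, decimals: int = 1) -> str:
    """Percent formatting with half-up rounding (presentation style)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return str(Decimal(x * 100).quantize(q, rounding=ROUND_HALF_UP))
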