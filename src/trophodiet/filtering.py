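"""Data-refinement cascade for metabarcoding MOTU tables.

Stomach-content and sediment eDNA read tables carry several classes of
artefact that must be removed before any diet statistic is meaningful:

* redundant MOTUs assigned to the same species (over-splitting by the
  upstream clustering);
* tag-switching (tag-jump) reads — small numbers of reads mis-assigned
  to the wrong multiplexed sample, producing low-count false positives;
* bacterial, human and terrestrial contaminant taxa;
* low-count cells indistinguishable from noise;
* MOTUs concentrated in PCR-negative controls (lab contamination);
* the consumer's own reads (and any dominant non-diet taxon such as a
  parasitic fungus), which would otherwise swamp relative abundances;
* samples whose diet-read depth is too low to be usable.

Each stage is individually invocable, returns a new table plus a
provenance record, and the cascade concatenates the records into a
:class:`FilterReport` whose read accounting reconciles exactly.

Inequality conventions follow the usual reporting wording: cells with
*four or fewer* reads are zeroed (``min_reads_per_cell=5`` keeps 5),
MOTUs *strictly above* 10% in negative controls are removed, samples
*strictly below* 1,000 diet reads are dropped.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .table import RANKS, MotuTable, ValidationError

DEFAULT_STAGE_ORDER = (
    "merge_species_motus",
    "renormalize_tag_switching",
    "remove_contaminants",
    "min_reads_filter",
    "negative_control_filter",
    "remove_focal_taxa",
    "sample_depth_filter",
)

#: taxa removed by default before diet analysis: the consumer itself and
#: the ubiquitous (likely endoparasitic) fungus found in its stomachs
DEFAULT_FOCAL_TAXA = ("Crangon crangon", "Purpureocillium lilacinum")

DEFAULT_CONTAMINANT_RULES = (
    {"rank": "kingdom", "name": "Bacteria"},
    {"rank": "species", "name": "Homo sapiens"},
)


class FilterError(ValueError):
    """A filter stage cannot proceed (e.g. nothing survives)."""


@dataclass
class FilterConfig:
    """Tunable thresholds and ordering of the refinement cascade.

    Attributes
    ----------
    tag_switch_threshold
        Per-MOTU row fraction below which a cell is treated as a tag
        jump and zeroed (default 0.01, strict inequality).
    negctrl_max_fraction
        Maximum tolerated fraction of a MOTU's reads in PCR-negative
        controls (default 0.10; removal is strict ``>``).
    min_reads_per_cell
        Smallest per-cell count retained (default 5: cells of four or
        fewer reads are zeroed).
    min_reads_mode
        ``"cell"`` zeroes individual cells (default); ``"motu"`` removes
        whole MOTUs whose row maximum is below the threshold.
    min_sample_depth
        Minimum post-focal-removal diet reads per sample (default 1000,
        strict ``<`` drops).
    depth_scope
        Sample types the depth rule applies to (default stomach only).
    drop_orphan_sediment
        After the depth filter, also drop sediment samples whose site no
        longer has any stomach sample (default True).
    focal_taxa
        Species names removed before diet statistics.
    contaminant_rules
        Taxonomy predicates, each ``{"rank": <taxonomy field>, "name": ...}``.
    stage_order
        Stage names applied, in order, by :func:`run_cascade`.
    """

    tag_switch_threshold: float = 0.01
    negctrl_max_fraction: float = 0.10
    min_reads_per_cell: int = 5
    min_reads_mode: str = "cell"
    min_sample_depth: int = 1000
    depth_scope: tuple[str, ...] = ("stomach",)
    drop_orphan_sediment: bool = True
    focal_taxa: tuple[str, ...] = DEFAULT_FOCAL_TAXA
    contaminant_rules: tuple[Mapping[str, str], ...] = DEFAULT_CONTAMINANT_RULES
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def __post_init__(self) -> None:
        if not (0 < self.tag_switch_threshold < 1):
            raise ValidationError("tag_switch_threshold must be in (0,1)")
        if not (0 < self.negctrl_max_fraction < 1):
            raise ValidationError("negctrl_max_fraction must be in (0,1)")
        if self.min_reads_per_cell < 1:
            raise ValidationError("min_reads_per_cell must be >= 1")
        if self.min_sample_depth < 0:
            raise ValidationError("min_sample_depth must be >= 0")
        if self.min_reads_mode not in ("cell", "motu"):
            raise ValidationError("min_reads_mode must be 'cell' or 'motu'")
        unknown = set(self.stage_order) - set(DEFAULT_STAGE_ORDER)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        d = dict(d)
        for key in ("depth_scope", "focal_taxa", "stage_order"):
            if key in d:
                d[key] = tuple(d[key])
        if "contaminant_rules" in d:
            d["contaminant_rules"] = tuple(dict(r) for r in d["contaminant_rules"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown filter config fields {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("depth_scope", "focal_taxa", "stage_order"):
            d[key] = list(d[key])
        d["contaminant_rules"] = [dict(r) for r in self.contaminant_rules]
        return d


@dataclass
class StageRecord:
    """Provenance for one cascade stage.

    Read accounting invariant::

        reads_in - reads_out ==  sum(removed_motus[*]["reads"])
                               + sum(removed_samples[*]["reads"])
                               + sum(zeroed_reads.values())
    """

    stage: str
    motus_in: int
    motus_out: int
    samples_in: int
    samples_out: int
    reads_in: int
    reads_out: int
    removed_motus: dict[str, dict] = field(default_factory=dict)
    removed_samples: dict[str, dict] = field(default_factory=dict)
    zeroed_reads: dict[str, int] = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def removed_read_total(self) -> int:
        return (
            sum(int(v["reads"]) for v in self.removed_motus.values())
            + sum(int(v["reads"]) for v in self.removed_samples.values())
            + sum(int(v) for v in self.zeroed_reads.values())
        )

    def reconciles(self) -> bool:
        return self.reads_in - self.reads_out == self.removed_read_total()


class FilterReport:
    """Ordered per-stage provenance for a (partial) cascade."""

    def __init__(self, records: Sequence[StageRecord] = ()) -> None:
        self.records: list[StageRecord] = list(records)

    def append(self, record: StageRecord) -> None:
        self.records.append(record)

    def extend(self, other: "FilterReport") -> None:
        self.records.extend(other.records)

    def validate_chain(self) -> None:
        """Check monotone read flow, stage chaining, and reconciliation."""
        prev: StageRecord | None = None
        for rec in self.records:
            if rec.reads_out > rec.reads_in:
                raise ValidationError(f"stage {rec.stage}: reads increased")
            if not rec.reconciles():
                raise ValidationError(
                    f"stage {rec.stage}: removed-read ledger does not "
                    f"reconcile ({rec.reads_in - rec.reads_out} removed, "
                    f"{rec.removed_read_total()} enumerated)"
                )
            if prev is not None and rec.reads_in != prev.reads_out:
                raise ValidationError(
                    f"stage {rec.stage}: reads_in != previous reads_out"
                )
            prev = rec

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = [dataclasses.asdict(r) for r in self.records]
        text = json.dumps(payload, indent=indent, default=str)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def summary(self) -> pd.DataFrame:
        cols = [
            "stage", "motus_in", "motus_out", "samples_in", "samples_out",
            "reads_in", "reads_out",
        ]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records]
        )


def _record(stage: str, before: MotuTable, after: MotuTable, **kw) -> StageRecord:
    return StageRecord(
        stage=stage,
        motus_in=before.n_motus,
        motus_out=after.n_motus,
        samples_in=before.n_samples,
        samples_out=after.n_samples,
        reads_in=before.total_reads(),
        reads_out=after.total_reads(),
        **kw,
    )


# ---------------------------------------------------------------------------
# stages


def merge_species_motus(table: MotuTable) -> tuple[MotuTable, StageRecord]:
    """Sum MOTUs assigned to the same species into one record.

    Only species-rank assignments are merged (two MOTUs assigned merely
    to the same genus stay separate).  The representative MOTU is the
    one with the highest best-identity score; total reads are conserved
    exactly.
    """
    tax = table.taxonomy
    is_sp = tax["rank"] == "species"
    removed: dict[str, dict] = {}
    counts = table.counts.copy()
    keep_tax = tax.copy()

    groups = tax.index[is_sp].to_series().groupby(tax.loc[is_sp, "species"])
    drop: list[str] = []
    for species, members in groups:
        members = list(members)
        if len(members) < 2:
            continue
        bi = tax.loc[members, "best_identity"]
        rep = bi.idxmax()
        others = [m for m in members if m != rep]
        counts.loc[rep] = counts.loc[members].sum(axis=0)
        for m in others:
            removed[m] = {
                "reason": f"merged into {rep} (species {species!r})",
                "reads": 0,  # transferred, not removed
            }
        drop.extend(others)

    counts = counts.drop(index=drop)
    keep_tax = keep_tax.drop(index=drop)
    out = MotuTable(counts, keep_tax, table.samples)
    return out, _record("merge_species_motus", table, out, removed_motus=removed)


def renormalize_tag_switching(
    table: MotuTable, threshold: float = 0.01
) -> tuple[MotuTable, StageRecord]:
    """Zero cells carrying a sub-threshold fraction of their MOTU's reads.

    Tag jumps leak a roughly constant small fraction of a template's
    reads into other libraries, so for each MOTU every cell whose count
    is strictly below ``threshold`` times the MOTU's total reads is
    treated as a false positive and set to zero.  A MOTU occupying a
    single cell is a fixed point (that cell holds 100% of its reads).
    """
    if not (0 < threshold < 1):
        raise ValidationError("threshold must be in (0,1)")
    counts = table.counts.to_numpy()
    totals = counts.sum(axis=1, keepdims=True)
    mask = (counts > 0) & (counts < threshold * totals)
    zeroed_per_motu = (counts * mask).sum(axis=1)
    new = counts.copy()
    new[mask] = 0
    out_counts = pd.DataFrame(
        new, index=table.counts.index, columns=table.counts.columns
    )
    zeroed = {
        m: int(z)
        for m, z in zip(table.counts.index, zeroed_per_motu)
        if z > 0
    }
    out = table.with_counts(out_counts)
    rec = _record(
        "renormalize_tag_switching", table, out,
        zeroed_reads=zeroed,
        details={"threshold": threshold, "cells_zeroed": int(mask.sum())},
    )
    return out, rec


def _match_rule(tax: pd.DataFrame, rule: Mapping[str, str]) -> pd.Series:
    rank = rule.get("rank")
    name = rule.get("name")
    if rank is None or name is None:
        raise ValidationError(f"contaminant rule needs 'rank' and 'name': {rule}")
    if rank not in RANKS:
        raise ValidationError(f"contaminant rule references unknown field {rank!r}")
    return tax[rank] == name


def remove_contaminants(
    table: MotuTable, rules: Sequence[Mapping[str, str]] = DEFAULT_CONTAMINANT_RULES
) -> tuple[MotuTable, StageRecord]:
    """Remove MOTUs matching any taxonomy predicate (whole rows).

    Rules are ``{"rank": <kingdom…species>, "name": <taxon name>}``; a
    bacterial-kingdom rule and a human blacklist are the defaults.
    """
    tax = table.taxonomy
    removed: dict[str, dict] = {}
    totals = table.motu_totals()
    for rule in rules:
        hit = _match_rule(tax, rule)
        for m in tax.index[hit]:
            if m not in removed:
                removed[m] = {
                    "reason": f"contaminant rule {rule['rank']}={rule['name']}",
                    "reads": int(totals[m]),
                }
    out = table.drop_motus(removed)
    return out, _record("remove_contaminants", table, out, removed_motus=removed)


def min_reads_filter(
    table: MotuTable, min_reads_per_cell: int = 5, mode: str = "cell"
) -> tuple[MotuTable, StageRecord]:
    """Remove low-count noise on a sample-by-sample basis.

    ``mode="cell"`` (default): every cell with fewer than
    ``min_reads_per_cell`` reads is zeroed; MOTUs whose rows become
    all-zero are dropped and listed.  ``mode="motu"``: a MOTU is removed
    outright when its row maximum is below the threshold.
    """
    if min_reads_per_cell < 1:
        raise ValidationError("min_reads_per_cell must be >= 1")
    counts = table.counts.to_numpy()
    if mode == "motu":
        row_max = counts.max(axis=1, initial=0)
        drop_mask = row_max < min_reads_per_cell
        totals = counts.sum(axis=1)
        removed = {
            m: {"reason": f"row maximum < {min_reads_per_cell}", "reads": int(t)}
            for m, t, d in zip(table.counts.index, totals, drop_mask)
            if d
        }
        out = table.drop_motus(removed)
        return out, _record("min_reads_filter", table, out, removed_motus=removed)
    if mode != "cell":
        raise ValidationError("mode must be 'cell' or 'motu'")

    mask = (counts > 0) & (counts < min_reads_per_cell)
    zeroed_per_motu = (counts * mask).sum(axis=1)
    new = counts.copy()
    new[mask] = 0
    all_zero = new.sum(axis=1) == 0
    zeroed = {
        m: int(z)
        for m, z in zip(table.counts.index, zeroed_per_motu)
        if z > 0
    }
    # rows dropped here have had all their reads zeroed above, so their
    # removal itself carries zero additional reads
    removed = {
        m: {"reason": "all cells below min reads", "reads": 0}
        for m, z in zip(table.counts.index, all_zero)
        if z
    }
    keep = table.counts.index[~all_zero]
    out_counts = pd.DataFrame(
        new[~all_zero], index=keep, columns=table.counts.columns
    )
    out = table.with_counts(out_counts)
    rec = _record(
        "min_reads_filter", table, out,
        removed_motus=removed, zeroed_reads=zeroed,
        details={"min_reads_per_cell": min_reads_per_cell,
                 "cells_zeroed": int(mask.sum())},
    )
    return out, rec


def negative_control_filter(
    table: MotuTable, max_fraction: float = 0.10
) -> tuple[MotuTable, StageRecord]:
    """Remove MOTUs over-represented in PCR-negative controls.

    A MOTU is removed from *all* samples when the fraction of its reads
    found in negative-control samples is strictly greater than
    ``max_fraction`` (a MOTU at exactly the threshold is retained).
    Control columns are consumed by this stage: they are dropped from
    the output and never reach diet statistics.  Without any control
    sample the stage is a logged no-op.
    """
    meta = table.samples
    ctrl = meta.index[meta["sample_type"] == "negative_control"]
    if len(ctrl) == 0:
        rec = _record(
            "negative_control_filter", table, table,
            details={"note": "no negative-control samples; stage skipped"},
        )
        return table.copy(), rec

    totals = table.motu_totals()
    in_ctrl = table.counts[ctrl].sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = in_ctrl / totals.replace(0, np.nan)
    flag = frac.fillna(0) > max_fraction
    removed = {
        m: {
            "reason": (
                f"{in_ctrl[m]}/{totals[m]} reads "
                f"({frac[m]:.1%}) in negative controls > {max_fraction:.0%}"
            ),
            "reads": int(totals[m]),
        }
        for m in table.counts.index[flag]
    }
    pruned = table.drop_motus(removed)
    # drop the consumed control columns; their residual reads are accounted
    ctrl_depths = pruned.counts[ctrl].sum(axis=0)
    removed_samples = {
        s: {"reason": "negative control consumed by stage", "reads": int(d)}
        for s, d in ctrl_depths.items()
    }
    keep = [s for s in pruned.sample_ids if s not in set(ctrl)]
    out = pruned.select_samples(keep)
    rec = _record(
        "negative_control_filter", table, out,
        removed_motus=removed, removed_samples=removed_samples,
        details={"max_fraction": max_fraction},
    )
    return out, rec


def remove_focal_taxa(
    table: MotuTable, focal_taxa: Sequence[str] = DEFAULT_FOCAL_TAXA
) -> tuple[MotuTable, StageRecord]:
    """Remove the consumer's own reads (and other designated taxa).

    Matching is by species name against species-rank assignments.  The
    record reports, per focal taxon and per sample, the pre-removal
    proportion of that taxon's reads — the classic "predator read
    fraction" summary — plus per-sample-type means and SDs.  A focal
    name that matches nothing triggers a warning, not a failure.
    """
    tax = table.taxonomy
    depths = table.sample_depths().astype(float)
    removed: dict[str, dict] = {}
    proportions: dict[str, dict[str, float]] = {}
    summaries: dict[str, dict] = {}
    totals = table.motu_totals()
    for name in focal_taxa:
        hit = (tax["rank"] == "species") & (tax["species"] == name)
        ids = list(tax.index[hit])
        if not ids:
            warnings.warn(f"focal taxon {name!r} matches no MOTU", stacklevel=2)
            continue
        focal_reads = table.counts.loc[ids].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = (focal_reads / depths.replace(0, np.nan)).fillna(0.0)
        proportions[name] = {s: float(p) for s, p in prop.items()}
        by_type = prop.groupby(table.samples["sample_type"], observed=True)
        summaries[name] = {
            t: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0}
            for t, v in by_type
        }
        for m in ids:
            removed[m] = {
                "reason": f"focal taxon {name}",
                "reads": int(totals[m]),
            }
    out = table.drop_motus(removed)
    rec = _record(
        "remove_focal_taxa", table, out,
        removed_motus=removed,
        details={
            "focal_proportions": proportions,
            "focal_proportion_summary": summaries,
        },
    )
    return out, rec


def sample_depth_filter(
    table: MotuTable,
    min_sample_depth: int = 1000,
    scope: Sequence[str] = ("stomach",),
) -> tuple[MotuTable, StageRecord]:
    """Drop in-scope samples whose read depth is strictly below the cutoff.

    Run after focal-taxon removal so the depth measures *diet* reads.
    Samples outside ``scope`` (e.g. sediment when scope is stomach) are
    never dropped by this stage.
    """
    if min_sample_depth < 0:
        raise ValidationError("min_sample_depth must be >= 0")
    depths = table.sample_depths()
    in_scope = table.samples["sample_type"].isin(set(scope))
    drop = table.sample_ids[in_scope & (depths < min_sample_depth)]
    removed_samples = {
        s: {
            "reason": f"read depth {int(depths[s])} < {min_sample_depth}",
            "reads": int(depths[s]),
        }
        for s in drop
    }
    keep = [s for s in table.sample_ids if s not in set(drop)]
    if not keep:
        raise FilterError("no samples survive depth filter")
    out = table.select_samples(keep)
    rec = _record(
        "sample_depth_filter", table, out,
        removed_samples=removed_samples,
        details={"min_sample_depth": min_sample_depth, "scope": list(scope)},
    )
    return out, rec


def drop_orphan_sediment(table: MotuTable) -> tuple[MotuTable, StageRecord]:
    """Drop sediment samples from sites with no remaining stomach sample.

    A site whose stomach pools all failed the depth filter contributes
    no diet observation, so its sediment sample cannot enter any paired
    statistic and is removed for consistency.
    """
    meta = table.samples
    stomach_sites = set(meta.loc[meta["sample_type"] == "stomach", "site"].dropna())
    is_sed = meta["sample_type"] == "sediment"
    orphan = meta.index[is_sed & ~meta["site"].isin(stomach_sites)]
    depths = table.sample_depths()
    removed_samples = {
        s: {
            "reason": f"sediment at site {meta.loc[s, 'site']!r} "
                      "with no surviving stomach sample",
            "reads": int(depths[s]),
        }
        for s in orphan
    }
    keep = [s for s in table.sample_ids if s not in set(orphan)]
    if not keep:
        raise FilterError("no samples survive orphan-sediment drop")
    out = table.select_samples(keep)
    return out, _record("drop_orphan_sediment", table, out,
                        removed_samples=removed_samples)


# ---------------------------------------------------------------------------
# cascade


def run_cascade(
    table: MotuTable, config: FilterConfig | None = None
) -> tuple[MotuTable, FilterReport]:
    """Apply the configured stages in order; return the diet table + report.

    The output table is the one consumed by the selectivity and
    community-statistics modules.  The concatenated report satisfies the
    chain-consistency invariant (validated before returning).
    """
    config = config or FilterConfig()
    stages: dict[str, Callable[[MotuTable], tuple[MotuTable, StageRecord]]] = {
        "merge_species_motus": merge_species_motus,
        "renormalize_tag_switching": lambda t: renormalize_tag_switching(
            t, config.tag_switch_threshold
        ),
        "remove_contaminants": lambda t: remove_contaminants(
            t, config.contaminant_rules
        ),
        "min_reads_filter": lambda t: min_reads_filter(
            t, config.min_reads_per_cell, config.min_reads_mode
        ),
        "negative_control_filter": lambda t: negative_control_filter(
            t, config.negctrl_max_fraction
        ),
        "remove_focal_taxa": lambda t: remove_focal_taxa(t, config.focal_taxa),
        "sample_depth_filter": lambda t: sample_depth_filter(
            t, config.min_sample_depth, config.depth_scope
        ),
    }
    report = FilterReport()
    current = table
    for name in config.stage_order:
        current, rec = stages[name](current)
        report.append(rec)
    if config.drop_orphan_sediment and "sample_depth_filter" in config.stage_order:
        if (current.samples["sample_type"] == "sediment").any():
            current, rec = drop_orphan_sediment(current)
            report.append(rec)
    report.validate_chain()
    return current, report
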