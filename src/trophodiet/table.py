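"""Core data model: the MOTU-by-sample read-count table.

A :class:`MotuTable` bundles three aligned pieces of information:

* ``counts`` — a non-negative integer matrix, rows indexed by MOTU id and
  columns by sample id;
* ``taxonomy`` — one row per MOTU: the assignment rank, the Linnaean path
  (kingdom … species, possibly partially empty), and the best-identity
  score of the reference-database match;
* ``samples`` — one row per sample: sample type (stomach, sediment,
  empty_stomach or negative_control), site, estuary, country, and the
  number of stomachs pooled into the sample.

It is the single currency passed between the filtering, selectivity and
community-statistics stages.  Construction validates the invariants; a
table that fails validation is never returned partially built.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: taxonomic ranks, most inclusive first
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: valid values of the taxonomy ``rank`` column
ASSIGNMENT_RANKS = frozenset(RANKS) | {"unassigned"}

SAMPLE_TYPES = frozenset(
    {"stomach", "sediment", "empty_stomach", "negative_control"}
)

TAXONOMY_COLUMNS = ("rank", *RANKS, "best_identity")
METADATA_COLUMNS = ("sample_type", "site", "estuary", "country", "pool_size")

MAX_POOL_SIZE = 8


class ValidationError(ValueError):
    """A table or one of its component frames violates an invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


class MotuTable:
    """Validated MOTU × sample read-count table with taxonomy and metadata.

    Parameters
    ----------
    counts
        DataFrame of read counts, index = MOTU ids, columns = sample ids.
        Values must be non-negative integers.
    taxonomy
        DataFrame indexed by MOTU id with columns ``rank``, the seven
        Linnaean ranks and ``best_identity``.  Index must match ``counts``
        rows exactly.
    samples
        DataFrame indexed by sample id with columns ``sample_type``,
        ``site``, ``estuary``, ``country``, ``pool_size``.  Index must
        match ``counts`` columns exactly.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        taxonomy: pd.DataFrame,
        samples: pd.DataFrame,
    ) -> None:
        counts = counts.copy()
        taxonomy = taxonomy.copy()
        samples = samples.copy()

        _check_unique(counts.index, "motu_id in counts")
        _check_unique(counts.columns, "sample_id in counts")
        _check_unique(taxonomy.index, "motu_id in taxonomy")
        _check_unique(samples.index, "sample_id in metadata")

        # exact key agreement between the three frames — missing or extra
        # ids are an error, never silently dropped
        motus_c, motus_t = set(counts.index), set(taxonomy.index)
        if motus_c != motus_t:
            missing = sorted(motus_c - motus_t)
            extra = sorted(motus_t - motus_c)
            raise ValidationError(
                f"taxonomy does not cover counts rows exactly: "
                f"missing={missing!r} extra={extra!r}"
            )
        samp_c, samp_m = set(counts.columns), set(samples.index)
        if samp_c != samp_m:
            missing = sorted(samp_c - samp_m)
            extra = sorted(samp_m - samp_c)
            raise ValidationError(
                f"metadata does not cover counts columns exactly: "
                f"missing={missing!r} extra={extra!r}"
            )

        # counts: integral, non-negative
        vals = counts.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.integer):
                flt = counts.astype(float).to_numpy()
                if not np.all(np.isfinite(flt)) or np.any(flt != np.floor(flt)):
                    raise ValidationError("non-integer count in counts matrix")
                counts = counts.astype(np.int64)
                vals = counts.to_numpy()
            if (vals < 0).any():
                bad = counts.stack()
                bad = bad[bad < 0].index[0]
                raise ValidationError(
                    f"negative count at motu {bad[0]!r}, sample {bad[1]!r}"
                )
        counts = counts.astype(np.int64) if vals.size else counts.astype(np.int64)

        missing_cols = [c for c in TAXONOMY_COLUMNS if c not in taxonomy.columns]
        if missing_cols:
            raise ValidationError(f"taxonomy missing columns {missing_cols}")
        missing_cols = [c for c in METADATA_COLUMNS if c not in samples.columns]
        if missing_cols:
            raise ValidationError(f"metadata missing columns {missing_cols}")

        bad_rank = set(taxonomy["rank"].dropna()) - ASSIGNMENT_RANKS
        if bad_rank:
            raise ValidationError(f"unknown taxonomy rank values {sorted(bad_rank)}")
        sp_rank = taxonomy["rank"] == "species"
        sp_names = taxonomy.loc[sp_rank, "species"]
        nameless = sp_names.index[sp_names.isna() | (sp_names == "")]
        if len(nameless):
            raise ValidationError(
                f"rank=species with empty species name: {list(nameless)}"
            )

        bi = pd.to_numeric(taxonomy["best_identity"], errors="coerce")
        bad = taxonomy.index[(bi < 0) | (bi > 1)]
        if len(bad):
            raise ValidationError(f"best_identity outside [0,1] for {list(bad)}")
        taxonomy["best_identity"] = bi

        bad_type = set(samples["sample_type"].dropna()) - SAMPLE_TYPES
        if bad_type:
            raise ValidationError(
                f"sample_type outside {sorted(SAMPLE_TYPES)}: {sorted(bad_type)}"
            )

        ps = pd.to_numeric(samples["pool_size"], errors="coerce").astype("Int64")
        bad = samples.index[ps.notna() & ((ps < 1) | (ps > MAX_POOL_SIZE))]
        if len(bad):
            raise ValidationError(
                f"pool_size outside [1,{MAX_POOL_SIZE}] for {list(bad)}"
            )
        samples["pool_size"] = ps

        # a site belongs to exactly one estuary
        site_map = samples[["site", "estuary"]].dropna().drop_duplicates()
        multi = site_map["site"][site_map["site"].duplicated()].unique().tolist()
        if multi:
            raise ValidationError(f"site mapped to multiple estuaries: {multi}")

        # canonical column order (extras, if any, keep their order at the end)
        tax_cols = [c for c in TAXONOMY_COLUMNS] + [
            c for c in taxonomy.columns if c not in TAXONOMY_COLUMNS
        ]
        meta_cols = [c for c in METADATA_COLUMNS] + [
            c for c in samples.columns if c not in METADATA_COLUMNS
        ]
        counts.index.name = "motu_id"
        counts.columns.name = None
        self.counts = counts
        self.taxonomy = taxonomy.loc[counts.index, tax_cols]
        self.taxonomy.index.name = "motu_id"
        self.samples = samples.loc[counts.columns, meta_cols]
        self.samples.index.name = "sample_id"

    # -- basic accessors ---------------------------------------------------

    @property
    def motu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_motus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def sample_depths(self) -> pd.Series:
        """Reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def motu_totals(self) -> pd.Series:
        """Reads per MOTU across all samples (row sums)."""
        return self.counts.sum(axis=1)

    # -- derived quantities ------------------------------------------------

    def relative_abundance(self, sample_id: str | None = None):
        """Per-MOTU read fractions within a sample (or all samples).

        Relative abundances are always derived from counts, never stored.
        Raises :class:`ValidationError` for a zero-depth sample.
        """
        if sample_id is not None:
            col = self.counts[sample_id]
            tot = int(col.sum())
            if tot == 0:
                raise ValidationError(f"zero-depth sample {sample_id!r}")
            return col / tot
        depths = self.sample_depths()
        zero = depths.index[depths == 0].tolist()
        if zero:
            raise ValidationError(f"zero-depth samples {zero}")
        return self.counts / depths

    # -- structural operations --------------------------------------------

    def subset(
        self,
        sample_types: Iterable[str] | None = None,
        sites: Iterable[str] | None = None,
    ) -> "MotuTable":
        """Restrict to samples matching the given types and/or sites.

        All-zero MOTU rows are retained: dropping MOTUs is an explicit
        filtering decision, never a side effect of subsetting.
        """
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        if sample_types is not None:
            sample_types = set(sample_types)
            unknown = sample_types - SAMPLE_TYPES
            if unknown:
                raise ValidationError(f"unknown sample types {sorted(unknown)}")
            absent = sample_types - set(meta["sample_type"])
            if absent:
                raise ValidationError(
                    f"sample types not present in table: {sorted(absent)}"
                )
            mask &= meta["sample_type"].isin(sample_types)
        if sites is not None:
            sites = set(sites)
            absent = sites - set(meta["site"].dropna())
            if absent:
                raise ValidationError(f"sites not present in table: {sorted(absent)}")
            mask &= meta["site"].isin(sites)
        keep = meta.index[mask]
        if len(keep) == 0:
            raise ValidationError("subset selects no samples")
        return MotuTable(self.counts[keep], self.taxonomy, meta.loc[keep])

    def select_samples(self, sample_ids: Sequence[str]) -> "MotuTable":
        """Restrict to an explicit sample-id list (order preserved)."""
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample ids {missing}")
        if len(sample_ids) == 0:
            raise ValidationError("empty sample selection")
        return MotuTable(
            self.counts[list(sample_ids)],
            self.taxonomy,
            self.samples.loc[list(sample_ids)],
        )

    def drop_motus(self, motu_ids: Iterable[str]) -> "MotuTable":
        drop = set(motu_ids)
        keep = [m for m in self.counts.index if m not in drop]
        return MotuTable(
            self.counts.loc[keep], self.taxonomy.loc[keep], self.samples
        )

    def with_counts(self, counts: pd.DataFrame) -> "MotuTable":
        """Same taxonomy/metadata, new counts (rows may be a subset)."""
        return MotuTable(
            counts,
            self.taxonomy.loc[counts.index],
            self.samples.loc[counts.columns],
        )

    def copy(self) -> "MotuTable":
        return MotuTable(self.counts, self.taxonomy, self.samples)

    def equals(self, other: "MotuTable") -> bool:
        if not isinstance(other, MotuTable):
            return False
        try:
            pd.testing.assert_frame_equal(self.counts, other.counts)
            pd.testing.assert_frame_equal(
                self.taxonomy, other.taxonomy, check_dtype=False
            )
            pd.testing.assert_frame_equal(
                self.samples, other.samples, check_dtype=False
            )
        except AssertionError:
            return False
        return True

    def __eq__(self, other: object) -> bool:  # pragma: no cover - delegation
        return isinstance(other, MotuTable) and self.equals(other)

    def __repr__(self) -> str:
        return (
            f"MotuTable({self.n_motus} MOTUs x {self.n_samples} samples, "
            f"{self.total_reads()} reads)"
        )


def species_name(taxonomy: pd.DataFrame, motu_id: str) -> str | None:
    """Species name of a MOTU, or None if not assigned at species rank."""
    row = taxonomy.loc[motu_id]
    if row["rank"] == "species":
        return row["species"]
    return None
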