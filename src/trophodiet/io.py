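"""Readers and writers for the TSV trio (counts, taxonomy, metadata).

File dialect: tab-separated, UTF-8, ``.`` decimal, one header row, no
quoting of numeric fields — the dialect the obitools/metabarcoding
ecosystem emits.  Counts are stored as integers; relative abundances are
always derived downstream, never written to the canonical table.

A deposited-archive layout may use different column names; adapt by
renaming columns to the canonical set before calling
:func:`read_motu_table` (``motu_id`` + sample columns for counts;
``motu_id``, ``rank``, kingdom…species, ``best_identity`` for taxonomy;
``sample_id``, ``sample_type``, ``site``, ``estuary``, ``country``,
``pool_size`` for metadata).
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .table import (
    METADATA_COLUMNS,
    RANKS,
    TAXONOMY_COLUMNS,
    MotuTable,
    ValidationError,
)

_COUNTS_SUFFIX = "_counts.tsv"
_TAXONOMY_SUFFIX = "_taxonomy.tsv"
_METADATA_SUFFIX = "_metadata.tsv"


def _read_tsv(path: str | os.PathLike, index_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if index_col not in df.columns:
        raise ValidationError(f"{path}: missing required column {index_col!r}")
    df = df.replace("", pd.NA)
    return df.set_index(index_col)


def read_motu_table(
    counts_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
) -> MotuTable:
    """Read and validate the counts/taxonomy/metadata TSV trio.

    Any disagreement between the three files (a sample column without
    metadata, a MOTU without taxonomy, a negative or fractional count)
    raises :class:`~trophodiet.table.ValidationError` naming the
    offending id — nothing is silently dropped.
    """
    counts = _read_tsv(counts_path, "motu_id")
    for col in counts.columns:
        ser = pd.to_numeric(counts[col], errors="coerce")
        bad = counts.index[ser.isna()].tolist()
        if bad:
            raise ValidationError(
                f"non-numeric count in sample {col!r} for MOTUs {bad}"
            )
        if (ser < 0).any():
            bad = counts.index[ser < 0][0]
            raise ValidationError(
                f"negative count at motu {bad!r}, sample {col!r}"
            )
        if (ser != ser.round()).any():
            bad = counts.index[ser != ser.round()][0]
            raise ValidationError(
                f"non-integer count at motu {bad!r}, sample {col!r}"
            )
        counts[col] = ser.astype("int64")

    taxonomy = _read_tsv(taxonomy_path, "motu_id")
    metadata = _read_tsv(metadata_path, "sample_id")
    return MotuTable(counts, taxonomy, metadata)


def write_motu_table(table: MotuTable, out_prefix: str | os.PathLike) -> dict[str, Path]:
    """Write a table as the TSV trio ``<prefix>_{counts,taxonomy,metadata}.tsv``.

    Round-trip safe: ``read_motu_table(*write_motu_table(t, p).values())``
    reproduces ``t`` bit-exactly (integer counts, identical metadata).
    Returns the written paths keyed by role.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": prefix.parent / (prefix.name + _COUNTS_SUFFIX),
        "taxonomy": prefix.parent / (prefix.name + _TAXONOMY_SUFFIX),
        "metadata": prefix.parent / (prefix.name + _METADATA_SUFFIX),
    }
    table.counts.rename_axis("motu_id").to_csv(paths["counts"], sep="\t")
    tax = table.taxonomy[list(TAXONOMY_COLUMNS)].rename_axis("motu_id")
    tax.to_csv(paths["taxonomy"], sep="\t")
    meta = table.samples[list(METADATA_COLUMNS)].rename_axis("sample_id")
    meta.to_csv(paths["metadata"], sep="\t")
    return paths


def read_representative_sequences(fasta_path: str | os.PathLike) -> dict[str, str]:
    """Optional FASTA of MOTU representative sequences, keyed by motu_id.

    Sequences are carried for provenance only; no computation uses them.
    """
    from Bio import SeqIO  # local import: biopython only needed here

    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate sequence id {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq)
    return seqs


def make_taxonomy_row(
    rank: str = "unassigned",
    best_identity: float = 1.0,
    **names: str,
) -> dict:
    """Convenience constructor for one taxonomy record (tests, simulator)."""
    row = {r: names.get(r, pd.NA) for r in RANKS}
    row["rank"] = rank
    row["best_identity"] = best_identity
    return row
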