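"""Readers and writers for the package's plain-text formats.

Formats
-------
* Isotope sample table: comma-separated, UTF-8, header required, columns
  ``sample_id, group, site_id, plot_id, role, tissue, delta13C, delta15N``
  (missing values as empty fields).
* OTU count table: TSV with a ``sample_id`` column, a ``group`` column and
  one integer column per OTU; taxonomy/guild in a sidecar TSV with columns
  ``otu_id, genus, family, guild``.
* Read sets: FASTA with vsearch-style ``;size=N`` abundance annotations.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError, ParseError
from .isotope import (
    EnrichmentRecord,
    IsotopeSample,
    MixingResult,
    records_to_frame,
    samples_to_frame,
)
from .metabarcoding import OtuTable, ReadRecord, ReadSet, parse_size_annotation

__all__ = [
    "read_isotope_csv",
    "write_isotope_csv",
    "write_enrichment_csv",
    "write_mixing_csv",
    "read_otu_table",
    "write_otu_table",
    "read_fasta_reads",
    "write_fasta_reads",
    "write_run_log",
]

ISOTOPE_COLUMNS = (
    "sample_id", "group", "site_id", "plot_id",
    "role", "tissue", "delta13C", "delta15N",
)


def read_isotope_csv(path) -> list[IsotopeSample]:
    """Read an isotope sample table; errors carry 1-based file line numbers."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed CSV {path}: {exc}") from exc
    missing = set(ISOTOPE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}", line=1)
    samples = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            samples.append(
                IsotopeSample(
                    sample_id=row["sample_id"],
                    group=row["group"],
                    site_id=row["site_id"],
                    plot_id=row["plot_id"],
                    role=row["role"],
                    tissue=row["tissue"] or "leaf",
                    delta13C=float(row["delta13C"]),
                    delta15N=float(row["delta15N"]),
                )
            )
        except (ValueError, InvalidInputError) as exc:
            raise ParseError(f"{path}: {exc}", line=line) from exc
    return samples


def write_isotope_csv(samples: Sequence[IsotopeSample], path) -> None:
    samples_to_frame(samples)[list(ISOTOPE_COLUMNS)].to_csv(path, index=False)


def write_enrichment_csv(records: Sequence[EnrichmentRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_mixing_csv(results: Sequence[MixingResult], path) -> None:
    pd.DataFrame(
        {
            "group": [r.group for r in results],
            "pcdf_mean": [r.pcdf_mean for r in results],
            "pcdf_sd": [r.pcdf_sd for r in results],
            "n": [r.n for r in results],
            "eps_fmh_baseline": [r.eps_fmh_baseline for r in results],
            "clamped": [r.clamped for r in results],
        }
    ).to_csv(path, index=False)


def read_otu_table(counts_path, taxonomy_path) -> OtuTable:
    """Read an OTU count TSV plus its taxonomy sidecar TSV."""
    try:
        counts = pd.read_csv(counts_path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"malformed TSV {counts_path}: {exc}") from exc
    for col in ("sample_id", "group"):
        if col not in counts.columns:
            raise ParseError(f"{counts_path}: missing {col!r} column", line=1)
    sample_meta = counts[["sample_id", "group"]].set_index("sample_id")
    mat = counts.drop(columns=["group"]).set_index("sample_id")
    for col in mat.columns:
        try:
            mat[col] = pd.to_numeric(mat[col], downcast=None).astype("int64")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(mat[col], errors="coerce").isna()
            line = int(bad.to_numpy().argmax()) + 2 if bad.any() else None
            raise ParseError(
                f"{counts_path}: non-integer count in column {col!r}", line=line
            ) from exc

    try:
        tax = pd.read_csv(taxonomy_path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"malformed TSV {taxonomy_path}: {exc}") from exc
    need = {"otu_id", "genus", "family", "guild"}
    if not need <= set(tax.columns):
        raise ParseError(
            f"{taxonomy_path}: missing columns {sorted(need - set(tax.columns))}",
            line=1,
        )
    return OtuTable(
        counts=mat, otu_meta=tax.set_index("otu_id"), sample_meta=sample_meta
    )


def write_otu_table(table: OtuTable, counts_path, taxonomy_path) -> None:
    out = table.counts.copy()
    out.insert(0, "group", table.sample_meta.loc[out.index, "group"])
    out.index.name = "sample_id"
    out.reset_index().to_csv(counts_path, sep="\t", index=False)
    tax = table.otu_meta.copy()
    tax.index.name = "otu_id"
    tax.reset_index().to_csv(taxonomy_path, sep="\t", index=False)


def read_fasta_reads(path) -> ReadSet:
    """Read a FASTA read set; abundance parsed from ``;size=N`` annotations."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        read_id, size = parse_size_annotation(rec.id)
        records.append(ReadRecord(read_id=read_id, sequence=str(rec.seq).upper(),
                                  abundance=size))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return ReadSet(records=records)


def write_fasta_reads(reads: ReadSet, path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=f"{r.read_id};size={r.abundance}",
                  description="")
        for r in reads
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_run_log(path, parameters: dict) -> None:
    """Machine-readable JSON log of a run's parameters and versions."""
    from . import __version__

    payload = {
        "mycomix_version": __version__,
        "python_version": platform.python_version(),
        "parameters": parameters,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
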