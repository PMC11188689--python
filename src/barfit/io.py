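"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; the tabular artifacts (pool table, count
matrix, sample sheet) are plain TSV/CSV handled with pandas. Pool tables are
written with 1-based positions (stated in the file header) and held 0-based
in memory, matching the genome annotation convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

POOL_COLUMNS = ["barcode", "rname", "pos", "strand", "n_support", "n_conflict", "gene_id"]
SAMPLE_SHEET_COLUMNS = ["sample_id", "water_sample", "condition", "day", "tech_rep"]


# ------------------------------------------------------------------ FASTA

def write_fasta(path: str | Path, name: str, sequence: str, description: str = "") -> None:
    rec = SeqRecord(Seq(sequence), id=name, description=description)
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (name, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


# ------------------------------------------------------------------ FASTQ

def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality-string) from a FASTQ file."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path: str | Path, reads: Iterator[tuple[str, str, str]]) -> int:
    """Write (title, sequence, quality-string) triples; returns read count."""
    n = 0
    with open(path, "w") as fh:
        for title, seq, qual in reads:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# -------------------------------------------------------------- pool table

def write_pool(path: str | Path, pool: pd.DataFrame) -> None:
    out = pool.copy()
    out["pos"] = out["pos"].astype(int) + 1  # 1-based on disk
    out["gene_id"] = out["gene_id"].fillna("") if "gene_id" in out else ""
    with open(path, "w") as fh:
        fh.write("# barcode pool table; pos is 1-based\n")
        out[POOL_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_pool(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            fh.seek(0)
        pool = pd.read_csv(fh, sep="\t", dtype={"barcode": str, "gene_id": str})
    pool["pos"] = pool["pos"].astype(int) - 1
    pool["gene_id"] = pool["gene_id"].where(pool["gene_id"].notna() & (pool["gene_id"] != ""), None)
    return pool


# ------------------------------------------------------------ count matrix

def write_count_matrix(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="barcode")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


# ------------------------------------------------------------ sample sheet

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "condition": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    sheet["day"] = sheet["day"].astype(int)
    return sheet


def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    sheet[SAMPLE_SHEET_COLUMNS].to_csv(path, index=False)
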