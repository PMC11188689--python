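"""BarSeq barcode counting.

The barcode sits at a known, fixed offset in each amplicon read; it is
extracted as a plain substring (no quality filter by default) and looked up
against the pool by exact string match — mismatching barcodes are discarded
but tallied, so the per-sample bookkeeping (matched + discarded +
unextractable = total reads) is exact.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import iter_fastq

BARCODE_LEN = 20


def extract_barcode_at_offset(read: str, offset: int) -> str | None:
    """The 20-mer at ``offset`` (0-based), or None when the read is too short."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if len(read) < offset + BARCODE_LEN:
        return None
    return read[offset : offset + BARCODE_LEN]


def count_barcodes(reads, pool: pd.DataFrame, offset: int = 0) -> tuple[pd.Series, dict]:
    """Count pool barcodes in one sample's reads.

    ``reads`` may be a FASTQ path or an iterable of read sequences. Returns
    a count Series in pool row order plus a summary dict with the mapped
    fraction (matched / extractable reads).
    """
    if len(pool) == 0:
        raise ConfigurationError("pool is empty")
    if isinstance(reads, (str, Path)):
        reads = (seq for _t, seq, _q in iter_fastq(reads))
    known = set(pool["barcode"])
    counts: Counter = Counter()
    total = extractable = matched = 0
    for seq in reads:
        total += 1
        bc = extract_barcode_at_offset(seq, offset)
        if bc is None:
            continue
        extractable += 1
        if bc in known:
            matched += 1
            counts[bc] += 1
    stats = {
        "total_reads": total,
        "extractable": extractable,
        "matched": matched,
        "discarded": extractable - matched,
        "unextractable": total - extractable,
        "mapped_fraction": matched / extractable if extractable else 0.0,
    }
    col = pd.Series(
        [counts.get(bc, 0) for bc in pool["barcode"]],
        index=pool["barcode"].to_numpy(),
        dtype=np.int64,
    )
    return col, stats


def assemble_count_matrix(
    columns: dict[str, pd.Series],
    sample_sheet: pd.DataFrame,
    pool: pd.DataFrame,
) -> pd.DataFrame:
    """Stack per-sample count columns into a barcode × sample matrix.

    Rows follow pool order; barcodes absent from a sample get 0. The sample
    sheet must cover every column, contain no duplicate sample ids, and
    provide exactly one Day-0 control per (water sample, technical
    replicate) lineage.
    """
    if sample_sheet["sample_id"].duplicated().any():
        raise ConfigurationError("duplicate sample ids in sample sheet")
    sheet_ids = set(sample_sheet["sample_id"])
    missing = set(columns) - sheet_ids
    if missing:
        raise ConfigurationError(f"samples not in sample sheet: {sorted(missing)[:5]}")
    lineages = sample_sheet[["water_sample", "tech_rep"]].drop_duplicates()
    controls = sample_sheet[sample_sheet["day"] == 0]
    n_controls = controls.groupby(["water_sample", "tech_rep"]).size()
    if len(n_controls) != len(lineages) or (n_controls != 1).any():
        raise ConfigurationError("need exactly one Day-0 control per (water sample, tech rep) lineage")
    index = pd.Index(pool["barcode"].to_numpy(), name="barcode")
    ordered = [sid for sid in sample_sheet["sample_id"] if sid in columns]
    data = {sid: columns[sid].reindex(index, fill_value=0).astype(np.int64) for sid in ordered}
    return pd.DataFrame(data, index=index)
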