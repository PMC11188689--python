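"""Build the barcode→insertion pool from transposon-junction reads.

Each read is expected to contain the constant priming sites U1 and U2 with
the random 20-bp barcode between them, followed by genomic sequence flanking
the insertion. Reads are screened for both sites and for barcode quality
(length exactly 20 bp and every base Q > 30, strictly); the genomic flank of
accepted reads is located on the reference by an exact-seed, bounded-
mismatch matcher over both strands, and barcodes are assigned their modal
position subject to support and purity thresholds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

U1 = "GATGTCCACGAGGTCTCT"
U2 = "CGTACGCTGCAGGTCGAC"

BARCODE_LEN = 20
QUALITY_MIN = 30  # strict: a base passes only if Q > 30

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SCAN_STATUSES = ("ok", "no-U1", "no-U2", "bad-length", "low-quality")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadScanResult:
    """Outcome of screening one mapping read.

    ``status`` is one of ``ok, no-U1, no-U2, bad-length, low-quality``
    (checked in that priority order); ``barcode`` and ``flank`` are only
    present where the corresponding part of the read could be located.
    """

    status: str
    barcode: str | None = None
    flank: str | None = None


def _quality_values(qualities) -> np.ndarray:
    if isinstance(qualities, str):
        return np.frombuffer(qualities.encode("ascii"), dtype=np.uint8).astype(int) - 33
    return np.asarray(qualities, dtype=int)


def scan_read(sequence: str, qualities) -> ReadScanResult:
    """Locate U1 and U2 and extract the barcode between them.

    The first exact occurrence of U1 is used, then the first exact
    occurrence of U2 after it; the intervening subsequence is the barcode
    candidate. Accepts qualities as a Phred+33 string or a sequence of
    integer Phred scores.
    """
    quals = _quality_values(qualities)
    if len(quals) != len(sequence):
        raise ValueError("sequence and qualities must have the same length")
    i = sequence.find(U1)
    if i < 0:
        return ReadScanResult("no-U1")
    j = sequence.find(U2, i + len(U1))
    if j < 0:
        return ReadScanResult("no-U2")
    barcode = sequence[i + len(U1) : j]
    if len(barcode) != BARCODE_LEN:
        return ReadScanResult("bad-length", barcode=barcode)
    bq = quals[i + len(U1) : j]
    if (bq <= QUALITY_MIN).any():
        return ReadScanResult("low-quality", barcode=barcode)
    return ReadScanResult("ok", barcode=barcode, flank=sequence[j + len(U2) :])


@dataclass
class FlankHit:
    """Result of placing a genomic flank on the reference.

    ``status``: ``hit``, ``short`` (flank below min_len), ``none`` (no locus
    within the mismatch budget), or ``ambiguous`` (two or more loci).
    ``position`` is the 0-based coordinate of the insertion junction — the
    reference base under the first flank base — and ``strand`` the strand
    the read came from.
    """

    status: str
    position: int | None = None
    strand: str | None = None


def _find_all(haystack: str, needle: str, limit: int) -> list[int]:
    out = []
    start = haystack.find(needle)
    while start != -1 and start < limit:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def align_flank(
    flank: str,
    reference: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    circular: bool = True,
) -> FlankHit:
    """Place a flank on the (circular) reference on either strand.

    The first ``min_len`` flank bases must match exactly (the seed); the
    remainder may carry up to ``max_mismatch`` substitutions. A unique locus
    is a hit; two or more loci within the budget are reported ambiguous.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    if len(flank) < min_len:
        return FlankHit("short")
    L = len(reference)
    flen = len(flank)
    doubled = reference + reference[: flen - 1] if circular else reference
    seed = flank[:min_len]
    candidates: set[tuple[int, str]] = set()

    for i in _find_all(doubled, seed, L):
        if i + flen <= len(doubled) and _mismatches(flank[min_len:], doubled[i + min_len : i + flen]) <= max_mismatch:
            candidates.add((i % L, "+"))

    # minus strand: the flank reads leftwards along the reference; an exact
    # seed match corresponds to revcomp(seed) ending the reverse-complement
    # window on the forward strand.
    rc = _revcomp(flank)
    rc_seed = rc[flen - min_len :]  # == revcomp(seed)
    for i in _find_all(doubled, rc_seed, L + flen):  # allow windows starting late
        start = i - (flen - min_len)
        if start < 0:
            if not circular:
                continue
            start += L
        if start + flen <= len(doubled) and _mismatches(rc[: flen - min_len], doubled[start : start + flen - min_len]) <= max_mismatch:
            candidates.add(((start + flen - 1) % L, "-"))

    if not candidates:
        return FlankHit("none")
    if len(candidates) > 1:
        return FlankHit("ambiguous")
    pos, strand = candidates.pop()
    return FlankHit("hit", position=pos, strand=strand)


def build_pool(
    reads,
    reference: str,
    min_support: int = 2,
    purity: float = 0.75,
    min_len: int = 30,
    max_mismatch: int = 3,
    rname: str = "chr",
) -> tuple[pd.DataFrame, dict]:
    """Group accepted reads by barcode and keep barcodes with a clean modal
    locus.

    ``reads`` is an iterable of ``(title, sequence, quality-string)``
    triples (as yielded by :func:`barfit.io.iter_fastq`). A barcode is kept
    when its modal (position, strand) is supported by at least
    ``min_support`` placed reads making up at least ``purity`` of all its
    placed reads. Returns the pool table plus per-reason bookkeeping that
    sums exactly to the number of input reads.
    """
    stats = {s: 0 for s in SCAN_STATUSES}
    stats.update({"flank-short": 0, "flank-none": 0, "flank-ambiguous": 0, "n_reads": 0})
    placements: dict[str, Counter] = {}
    for _title, seq, qual in reads:
        stats["n_reads"] += 1
        scan = scan_read(seq, qual)
        stats[scan.status] += 1
        if scan.status != "ok":
            continue
        hit = align_flank(scan.flank, reference, min_len=min_len, max_mismatch=max_mismatch)
        if hit.status != "hit":
            stats[f"flank-{hit.status}"] += 1
            continue
        placements.setdefault(scan.barcode, Counter())[(hit.position, hit.strand)] += 1

    rows = []
    dropped_support = dropped_purity = 0
    for bc in sorted(placements):
        locus_counts = placements[bc]
        # modal locus; ties broken toward the lowest coordinate for determinism
        best = max(locus_counts.items(), key=lambda kv: (kv[1], -kv[0][0], kv[0][1]))
        (pos, strand), n_support = best
        n_conflict = sum(locus_counts.values()) - n_support
        if n_support < min_support:
            dropped_support += 1
            continue
        if n_support / (n_support + n_conflict) < purity:
            dropped_purity += 1
            continue
        rows.append((bc, rname, pos, strand, n_support, n_conflict, None))
    stats["barcodes_seen"] = len(placements)
    stats["dropped_low_support"] = dropped_support
    stats["dropped_low_purity"] = dropped_purity
    stats["barcodes_kept"] = len(rows)
    if stats["n_reads"] == 0:
        import warnings

        warnings.warn("empty input: building an empty pool", stacklevel=2)
    pool = pd.DataFrame(
        rows, columns=["barcode", "rname", "pos", "strand", "n_support", "n_conflict", "gene_id"]
    )
    return pool, stats


def assign_genes(pool: pd.DataFrame, annotation, central_trim: tuple[float, float] | None = None) -> pd.DataFrame:
    """Attach gene ids to pool rows whose insertion falls inside a gene body
    (optionally restricted to a central fraction of the gene). Intergenic
    barcodes keep ``gene_id = None`` and stay in the pool; downstream gene
    fitness simply ignores them.
    """
    out = pool.copy()
    out["gene_id"] = annotation.assign(out["pos"].to_numpy(), central_trim=central_trim)
    return out
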