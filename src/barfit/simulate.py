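"""Synthetic RB-TnSeq data with known ground truth.

Generates circular genomes with non-overlapping gene annotations, barcoded
Tn5 insertion libraries with lognormal strain abundances, selection dynamics
with per-gene log2 fitness effects, and the two read types the assay
produces:

* *mapping* reads (transposon junction): U1 + 20-bp barcode + U2 + genomic
  flank, used to build the barcode→position pool;
* *BarSeq* reads: the barcode at a fixed offset in a short amplicon read,
  used for cheap abundance counting.

Selection is modeled directly on log2 abundance change per (condition, day)
relative to Day 0: strain *i* carrying a gene with effect *e* has abundance
``a_i(0) · 2^e`` renormalized to sum 1. Sequencing noise is multinomial at
the requested depth. Every output is accompanied by a truth sidecar so each
downstream stage can be checked without re-simulation, and all randomness
flows from an explicit seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError, SizingError
from .genome import GenomeAnnotation
from .io import write_fasta, write_fastq
from .tnmap import U1, U2

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Defect categories a mapping read can be seeded with. Labels match the
# rejection reasons reported by tnmap.
DEFECT_CATEGORIES = ("no-U2", "bad-length", "low-quality", "bad-flank")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng) -> str:
    rng = _rng(rng)
    idx = rng.integers(0, 4, size=length, dtype=np.uint8)
    return _BASES[idx].tobytes().decode("ascii")


@dataclass
class SimConfig:
    """Knobs of one synthetic study; defaults mirror the desk-scale design
    (3 Mb genome, 3000 genes, 60 000 insertions, 2×10^6 reads per sample)."""

    genome_length: int = 3_000_000
    n_genes: int = 3000
    n_insertions: int = 60_000
    barcode_length: int = 20
    coding_fraction: float = 0.9
    abundance_sigma: float = 1.0
    read_depth: int = 2_000_000
    error_rate: float = 0.0
    seed: int = 0
    effect_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.barcode_length != 20:
            raise ConfigurationError("barcode_length must be 20 (the assay's barcode definition)")


# ----------------------------------------------------------------- genome

def simulate_genome(
    length: int,
    n_genes: int,
    seed,
    min_gene_len: int = 300,
    max_coding_density: float = 0.9,
    name: str = "chr",
    fasta_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
) -> tuple[GenomeAnnotation, str]:
    """Random circular chromosome with ``n_genes`` non-overlapping genes.

    Genes are laid out one per equal slot along the chromosome with random
    length (>= ``min_gene_len``) and offset, which guarantees no overlaps and
    at least 1 bp of intergenic space between neighbours.
    """
    rng = _rng(seed)
    if n_genes < 1:
        raise SizingError("n_genes must be >= 1")
    slot = length // n_genes
    max_len = int(slot * max_coding_density)
    if max_len < min_gene_len or slot < min_gene_len + 2:
        raise SizingError(
            f"genome length {length} too small to tile {n_genes} genes of >= {min_gene_len} bp"
        )
    gene_len = rng.integers(min_gene_len, max_len + 1, size=n_genes)
    offset = rng.integers(0, slot - gene_len + 1)
    start = np.arange(n_genes, dtype=np.int64) * slot + offset
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    width = len(str(n_genes))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(n_genes)],
            "start": start,
            "end": start + gene_len,
            "strand": strand,
        }
    )
    annotation = GenomeAnnotation(length=length, genes=genes)
    sequence = random_sequence(length, rng)
    if fasta_path is not None:
        write_fasta(fasta_path, name, sequence, description="synthetic circular chromosome")
    if annotation_path is not None:
        annotation.to_tsv(annotation_path)
    return annotation, sequence


# ---------------------------------------------------------------- library

def _coding_intervals(annotation: GenomeAnnotation) -> tuple[np.ndarray, np.ndarray]:
    starts = annotation.genes["start"].to_numpy()
    ends = annotation.genes["end"].to_numpy()
    return starts, ends


def _sample_positions(annotation, rng):
    """Return draw functions for uniform positions over coding and
    intergenic bases respectively."""
    starts, ends = _coding_intervals(annotation)
    lens = ends - starts
    cum = np.concatenate([[0], np.cumsum(lens)])
    total_coding = int(cum[-1])
    # intergenic gaps (circular: last gap wraps to first gene)
    gap_starts = ends
    gap_ends = np.concatenate([starts[1:], [annotation.length + starts[0]]]) if len(starts) else np.array([])
    gap_lens = gap_ends - gap_starts
    gcum = np.concatenate([[0], np.cumsum(gap_lens)])
    total_gap = int(gcum[-1])
    def draw_coding(k):
        if total_coding == 0:
            raise SizingError("annotation has no coding bases")
        off = rng.integers(0, total_coding, size=k)
        i = np.searchsorted(cum, off, side="right") - 1
        return starts[i] + (off - cum[i])

    def draw_gap(k):
        if total_gap == 0:
            raise SizingError("annotation has no intergenic bases")
        off = rng.integers(0, total_gap, size=k)
        i = np.searchsorted(gcum, off, side="right") - 1
        return (gap_starts[i] + (off - gcum[i])) % annotation.length

    return draw_coding, draw_gap


def _unique_draw(draw, k, seen: set, max_rounds: int = 60) -> list:
    out = []
    for _ in range(max_rounds):
        need = k - len(out)
        if need == 0:
            return out
        for v in draw(need):
            v = int(v) if not isinstance(v, str) else v
            if v not in seen:
                seen.add(v)
                out.append(v)
    if len(out) < k:
        raise GenerationError("could not draw enough unique values after bounded retries")
    return out


def random_barcodes(n: int, length: int, rng, seen: set | None = None) -> list[str]:
    rng = _rng(rng)
    seen = set() if seen is None else seen

    def draw(k):
        idx = rng.integers(0, 4, size=(k, length), dtype=np.uint8)
        rows = _BASES[idx]
        return [rows[i].tobytes().decode("ascii") for i in range(k)]

    return _unique_draw(draw, n, seen)


def simulate_library(
    annotation: GenomeAnnotation,
    n_insertions: int,
    coding_fraction: float = 0.9,
    seed=0,
    barcode_length: int = 20,
    abundance_sigma: float = 1.0,
    rname: str = "chr",
) -> tuple[pd.DataFrame, pd.Series]:
    """Barcoded insertion pool plus initial strain abundances.

    Each insertion lands in a gene body with probability ``coding_fraction``
    (uniform over coding bases) and intergenic otherwise; positions and
    20-mer barcodes are unique. Initial abundances are lognormal(0, sigma)
    normalized to sum 1 — the heavy-tailed strain representation typical of
    transposon pools.
    """
    rng = _rng(seed)
    if not (0.0 < coding_fraction <= 1.0):
        raise ConfigurationError("coding_fraction must be in (0, 1]")
    if n_insertions > annotation.length:
        raise SizingError("more insertions than genome positions")
    draw_coding, draw_gap = _sample_positions(annotation, rng)
    in_gene = rng.random(n_insertions) < coding_fraction
    n_cod = int(in_gene.sum())
    seen: set = set()
    pos = np.empty(n_insertions, dtype=np.int64)
    pos[in_gene] = _unique_draw(draw_coding, n_cod, seen)
    pos[~in_gene] = _unique_draw(draw_gap, n_insertions - n_cod, seen)
    barcodes = random_barcodes(n_insertions, barcode_length, rng)
    strand = np.where(rng.random(n_insertions) < 0.5, "+", "-")
    gene_id = annotation.assign(pos)
    pool = pd.DataFrame(
        {
            "barcode": barcodes,
            "rname": rname,
            "pos": pos,
            "strand": strand,
            "n_support": 0,
            "n_conflict": 0,
            "gene_id": gene_id,
        }
    )
    raw = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_insertions)
    abundances = pd.Series(raw / raw.sum(), index=pool["barcode"].to_numpy(), name="abundance")
    return pool, abundances


# -------------------------------------------------------------- selection

def strain_effects(pool: pd.DataFrame, effect_map: dict, condition: str, day: int) -> np.ndarray:
    """Per-strain log2 effect at (condition, day); 0 for intergenic strains
    and genes absent from the map."""
    e = np.zeros(len(pool))
    if day == 0 or not effect_map:
        return e
    by_gene = {g: eff.get((condition, day), 0.0) for g, eff in effect_map.items()}
    genes = pool["gene_id"].to_numpy()
    for i, g in enumerate(genes):
        if g is not None and g in by_gene:
            e[i] = by_gene[g]
    return e


def validate_effect_map(effect_map: dict, annotation: GenomeAnnotation) -> None:
    known = set(annotation.genes["gene_id"])
    unknown = sorted(set(effect_map) - known)
    if unknown:
        raise ConfigurationError(f"effect_map refers to unknown genes: {unknown[:5]}")
    for g, eff in effect_map.items():
        for key, e in eff.items():
            if not np.isfinite(e):
                raise ConfigurationError(f"non-finite effect for gene {g} at {key}")


def simulate_selection(
    abundances: pd.Series,
    effect_map: dict,
    schedule: list[tuple[str, int]],
    pool: pd.DataFrame,
    annotation: GenomeAnnotation | None = None,
) -> dict[tuple[str, int], pd.Series]:
    """Expected strain proportions at each (condition, day) of the schedule.

    Day 0 entries return the initial proportions unchanged (effects are
    defined relative to Day 0). Other entries multiply each strain's initial
    abundance by 2^effect and renormalize, so a strain's expected measured
    fitness equals its gene's true effect up to the common normalization
    constant.
    """
    if not any(day == 0 for _, day in schedule):
        raise ConfigurationError("schedule must include Day 0")
    if annotation is not None:
        validate_effect_map(effect_map, annotation)
    a0 = abundances.to_numpy(dtype=float)
    a0 = a0 / a0.sum()
    out: dict[tuple[str, int], pd.Series] = {}
    for condition, day in schedule:
        if day == 0:
            p = a0
        else:
            e = strain_effects(pool, effect_map, condition, day)
            w = a0 * np.exp2(e)
            p = w / w.sum()
        out[(condition, day)] = pd.Series(p, index=abundances.index, name=f"{condition}_d{day}")
    return out


def draw_counts(proportions, depth: int, rng) -> np.ndarray:
    """Multinomial sequencing noise: counts sum to ``depth`` exactly."""
    rng = _rng(rng)
    p = np.asarray(proportions, dtype=float)
    if depth < 0:
        raise ConfigurationError("depth must be >= 0")
    if depth == 0:
        return np.zeros(len(p), dtype=np.int64)
    return rng.multinomial(depth, p / p.sum())


# ---------------------------------------------------------- mapping reads

def _flank_at(sequence: str, pos: int, strand: str, flank_len: int) -> str:
    """Genomic sequence downstream of the insertion point on the read's
    strand, with circular wrap; the first flank base sits at ``pos``."""
    L = len(sequence)
    if strand == "+":
        if pos + flank_len <= L:
            return sequence[pos : pos + flank_len]
        return (sequence + sequence)[pos : pos + flank_len]
    # minus strand: downstream runs leftward; revcomp of [pos-flank+1, pos]
    start = pos - flank_len + 1
    if start >= 0:
        window = sequence[start : pos + 1]
    else:
        window = sequence[start % L :] + sequence[: pos + 1]
    return revcomp(window)


def _mutate(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < error_rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        base_idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def write_mapping_fastq(
    pool: pd.DataFrame,
    sequence: str,
    n_reads: int,
    error_rate: float = 0.0,
    invalid_mix: dict | None = None,
    seed=0,
    path: str | Path = "mapping.fastq",
    truth_path: str | Path | None = None,
    flank_len: int = 50,
) -> pd.DataFrame:
    """Write transposon-junction reads (U1+barcode+U2+flank) plus a truth
    sidecar giving each read's category and planted position.

    ``invalid_mix`` maps defect category → count; the remaining reads are
    clean and distributed round-robin over the pool so every insertion is
    covered evenly. Qualities are Q40 except the single Q30 base seeded in
    ``low-quality`` reads. Substitution errors (``error_rate``) apply to the
    genomic flank only.
    """
    rng = _rng(seed)
    invalid_mix = dict(invalid_mix or {})
    unknown = set(invalid_mix) - set(DEFECT_CATEGORIES)
    if unknown:
        raise ConfigurationError(f"unknown defect categories: {sorted(unknown)}")
    n_bad = int(sum(invalid_mix.values()))
    if n_reads < n_bad:
        raise SizingError("n_reads smaller than the number of seeded defects")
    n_clean = n_reads - n_bad

    pos = pool["pos"].to_numpy()
    strands = pool["strand"].to_numpy()
    bcs = pool["barcode"].to_numpy()
    n_pool = len(pool)
    q40 = "I" * (len(U1) + 20 + len(U2) + flank_len)

    records = []  # (category, barcode, pos, strand, seq, qual)
    for r in range(n_clean):
        i = r % n_pool
        flank = _mutate(_flank_at(sequence, int(pos[i]), strands[i], flank_len), error_rate, rng)
        seq = U1 + bcs[i] + U2 + flank
        records.append(("ok", bcs[i], int(pos[i]), strands[i], seq, q40))

    bad_barcodes = random_barcodes(
        invalid_mix.get("bad-flank", 0), 20, rng, seen=set(bcs)
    )
    for category, count in invalid_mix.items():
        for k in range(count):
            i = int(rng.integers(0, n_pool))
            flank = _mutate(_flank_at(sequence, int(pos[i]), strands[i], flank_len), error_rate, rng)
            if category == "no-U2":
                # replace U2 and make sure no spurious U2 arises downstream
                while U2 in bcs[i] + "A" * len(U2) + flank:
                    i = int(rng.integers(0, n_pool))
                    flank = _mutate(_flank_at(sequence, int(pos[i]), strands[i], flank_len), error_rate, rng)
                seq = U1 + bcs[i] + "A" * len(U2) + flank
                records.append((category, bcs[i], int(pos[i]), strands[i], seq, "I" * len(seq)))
            elif category == "bad-length":
                seq = U1 + bcs[i][:19] + U2 + flank
                records.append((category, bcs[i][:19], int(pos[i]), strands[i], seq, "I" * len(seq)))
            elif category == "low-quality":
                seq = U1 + bcs[i] + U2 + flank
                qual = list(q40)
                qual[len(U1) + int(rng.integers(0, 20))] = "?"  # '?' is Q30; the filter is strict Q>30
                records.append((category, bcs[i], int(pos[i]), strands[i], seq, "".join(qual)))
            elif category == "bad-flank":
                bc = bad_barcodes[k]
                seq = U1 + bc + U2 + random_sequence(flank_len, rng)
                records.append((category, bc, -1, ".", seq, "I" * len(seq)))

    order = rng.permutation(len(records))
    truth_rows = []
    reads = []
    for out_i, rec_i in enumerate(order):
        category, bc, p, s, seq, qual = records[rec_i]
        rid = f"read{out_i:07d}"
        reads.append((rid, seq, qual))
        truth_rows.append((rid, category, bc, p + 1 if p >= 0 else 0, s))
    write_fastq(path, iter(reads))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "category", "barcode", "pos", "strand"])
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("# mapping-read truth sidecar; pos is 1-based (0 = not applicable)\n")
            truth.to_csv(fh, sep="\t", index=False)
    return truth


# ----------------------------------------------------------- BarSeq reads

def write_barseq_reads(
    abundances: pd.Series,
    depth: int,
    offset: int = 10,
    seed=0,
    path: str | Path | None = None,
    read_len: int | None = None,
) -> pd.Series:
    """Draw multinomial(depth, abundances) barcode counts; optionally also
    write a FASTQ with each barcode at the given 0-based offset, padded by a
    fixed sequence (Q40 throughout). Returns the count table, which is the
    exact ground truth for the written reads.
    """
    rng = _rng(seed)
    counts = draw_counts(abundances.to_numpy(), depth, rng)
    series = pd.Series(counts, index=abundances.index, name="count")
    if path is not None:
        bc_len = len(str(abundances.index[0])) if len(abundances) else 20
        if read_len is None:
            read_len = offset + bc_len + 10
        if read_len < offset + bc_len:
            raise ConfigurationError("read_len shorter than offset + barcode length")
        pad = ("ACGT" * (read_len // 4 + 2))[:read_len]
        qual = "I" * read_len
        def reads():
            n = 0
            for bc, c in series.items():
                tail = pad[offset + bc_len :]
                seq = pad[:offset] + bc + tail
                for _ in range(int(c)):
                    yield (f"bs{n:08d}", seq, qual)
                    n += 1
        write_fastq(path, reads())
    return series
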