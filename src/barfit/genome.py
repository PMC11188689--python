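"""Genome annotation container used across the pipeline.

The chromosome is treated as circular (as in *E. coli*). Coordinates are
0-based half-open in memory; annotation files on disk use 1-based inclusive
coordinates, the usual convention for GFF-like tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["gene_id", "start", "end", "strand"]


@dataclass
class GenomeAnnotation:
    """A circular chromosome length plus non-overlapping gene records.

    Parameters
    ----------
    length : int
        Chromosome length in bp.
    genes : pandas.DataFrame
        Columns ``gene_id, start, end, strand`` with 0-based half-open
        coordinates, sorted by ``start``. Genes must not overlap and must not
        wrap the origin.
    """

    length: int
    genes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        g = self.genes.reset_index(drop=True)
        missing = [c for c in ANNOTATION_COLUMNS if c not in g.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        g = g[ANNOTATION_COLUMNS].copy()
        g["start"] = g["start"].astype(np.int64)
        g["end"] = g["end"].astype(np.int64)
        if len(g):
            if g["gene_id"].duplicated().any():
                raise ValueError("duplicate gene ids in annotation")
            if not (g["start"] < g["end"]).all():
                raise ValueError("gene start must be < end (0-based half-open)")
            if g["start"].min() < 0 or g["end"].max() > self.length:
                raise ValueError("gene coordinates outside the chromosome")
            g = g.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError("annotation contains overlapping genes")
        self.genes = g

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def midpoints(self) -> pd.Series:
        """Gene chromosomal midpoints, ``(start + end) // 2``, indexed by gene id.

        This is the ordering key for chromosomal normalization; ties are
        broken by ``start`` (already encoded in the stored sort order).
        """
        mid = (self.genes["start"] + self.genes["end"]) // 2
        return pd.Series(mid.to_numpy(), index=self.genes["gene_id"].to_numpy(), name="midpoint")

    def gene_order(self) -> list[str]:
        """Gene ids sorted by chromosomal midpoint (ties by start)."""
        m = self.midpoints()
        order = np.lexsort((self.genes["start"].to_numpy(), m.to_numpy()))
        return [m.index[i] for i in order]

    def assign(self, positions, central_trim: tuple[float, float] | None = None) -> np.ndarray:
        """Map genomic positions to gene ids.

        A position is assigned to a gene iff it lies within the gene body
        (start inclusive, end exclusive in 0-based half-open terms, i.e. the
        gene's first through last base). With ``central_trim=(lo, hi)`` only
        insertions whose relative position within the gene falls in
        ``[lo, hi)`` are assigned — the conventional trim that discards
        insertions near gene termini which may not disrupt function.

        Returns an object array of gene ids, with ``None`` for intergenic
        positions.
        """
        pos = np.asarray(positions, dtype=np.int64)
        if len(pos) and (pos.min() < 0 or pos.max() >= self.length):
            raise ValueError("position outside the chromosome")
        out = np.full(pos.shape, None, dtype=object)
        if not self.n_genes:
            return out
        starts = self.genes["start"].to_numpy()
        ends = self.genes["end"].to_numpy()
        ids = self.genes["gene_id"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(pos.shape, dtype=bool)
        inside[ok] = pos[ok] < ends[idx[ok]]
        if central_trim is not None:
            lo, hi = central_trim
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("central_trim must satisfy 0 <= lo < hi <= 1")
            frac = np.zeros(pos.shape)
            frac[ok] = (pos[ok] - starts[idx[ok]]) / (ends[idx[ok]] - starts[idx[ok]])
            inside &= (frac >= lo) & (frac < hi)
        out[inside] = ids[idx[inside]]
        return out

    # ---------------------------------------------------------------- I/O

    def to_tsv(self, path: str | Path) -> None:
        """Write a GFF-like TSV with 1-based inclusive coordinates."""
        out = self.genes.copy()
        out["start"] = out["start"] + 1  # 1-based inclusive on disk
        header = f"# circular chromosome, length={self.length}; coordinates 1-based inclusive\n"
        with open(path, "w") as fh:
            fh.write(header)
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, length: int | None = None) -> "GenomeAnnotation":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                if length is None and "length=" in first:
                    length = int(first.split("length=")[1].split(";")[0])
                genes = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                genes = pd.read_csv(fh, sep="\t")
        if length is None:
            raise ValueError("chromosome length not given and not recorded in file header")
        genes["start"] = genes["start"] - 1  # back to 0-based half-open
        return cls(length=int(length), genes=genes)
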