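"""PCA-based selection of reproducibly enriched/depleted mutants.

Per biological replicate (water sample) the gene × (condition, day) fitness
matrix is column-mean-centered and decomposed by PCA. PC signs are arbitrary
under SVD, so a deterministic orientation is imposed: (a) the mean PC1
loading over all columns is negative — depleted genes then score positive on
PC1 — and (b) the mean PC2 loading of filtered-water columns exceeds that of
non-filtered columns, so filtered-specific enrichment points into Quadrant
II. Quadrants of the (PC1, PC2) plane then carry the usual semantics:
I and IV depletion, II and III enrichment (in non-filtered resp. filtered
water). Genes are ranked by Euclidean distance from the origin in the PC1–
PC2 plane; the consensus sets collect genes in the top 5% of every
replicate with a consistent quadrant class — "blue" (depleted, quadrants
I/IV) and "red" (enriched, quadrants II/III).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigurationError, OrientationError

FILTERED = "filtered"
NON_FILTERED = "non-filtered"
QUADRANTS = ("I", "II", "III", "IV")
DEPLETED_QUADRANTS = frozenset({"I", "IV"})
ENRICHED_QUADRANTS = frozenset({"II", "III"})


def column_order(conditions=(FILTERED, NON_FILTERED), days=(2, 4, 8)) -> list[tuple[str, int]]:
    return [(c, d) for c in conditions for d in days]


def assemble_matrix(
    gene_table: pd.DataFrame,
    water_sample=None,
    value: str = "f_norm",
    conditions=(FILTERED, NON_FILTERED),
    days=(2, 4, 8),
) -> pd.DataFrame:
    """Pivot replicate-averaged gene fitness into a gene × (condition, day)
    matrix with a fixed column order; genes with any missing cell are
    dropped (count recorded in ``.attrs['n_dropped']``)."""
    t = gene_table
    if water_sample is not None:
        t = t[t["water_sample"] == water_sample]
    wide = t.pivot_table(index="gene", columns=["condition", "day"], values=value)
    cols = column_order(conditions, days)
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise ConfigurationError(f"missing (condition, day) cells: {missing}")
    wide = wide[cols]
    complete = wide.dropna()
    complete.attrs["n_dropped"] = len(wide) - len(complete)
    return complete


@dataclass
class PcaResult:
    """Scores and loadings of the first two PCs plus all variance fractions."""

    scores: pd.DataFrame  # gene × [PC1, PC2]
    loadings: pd.DataFrame  # (condition, day) column × [PC1, PC2], orthonormal columns
    variance_fraction: np.ndarray  # one entry per computed PC, sums to 1
    columns: list = field(default_factory=list)


def run_pca(matrix: pd.DataFrame, scale: bool = False) -> PcaResult:
    """Column-mean-centered PCA (no variance scaling by default — the
    columns share log2-fitness units)."""
    if matrix.shape[0] < 3:
        raise ConfigurationError("PCA needs at least 3 genes")
    if matrix.shape[1] < 2:
        raise ConfigurationError("PCA needs at least 2 columns")
    X = matrix.to_numpy(dtype=float)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=min(X.shape[0], X.shape[1]), svd_solver="full")
    proj = pca.fit_transform(X)
    scores = pd.DataFrame(proj[:, :2], index=matrix.index, columns=["PC1", "PC2"])
    loadings = pd.DataFrame(
        pca.components_[:2].T, index=matrix.columns, columns=["PC1", "PC2"]
    )
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=pca.explained_variance_ratio_.copy(),
        columns=list(matrix.columns),
    )


def orient(result: PcaResult, filtered_label: str = FILTERED) -> PcaResult:
    """Fix PC signs deterministically (see module docstring)."""
    scores = result.scores.copy()
    loadings = result.loadings.copy()
    m1 = loadings["PC1"].mean()
    if m1 == 0:
        raise OrientationError("mean PC1 loading is zero; orientation undefined")
    if m1 > 0:
        scores["PC1"] *= -1
        loadings["PC1"] *= -1
    is_filtered = np.array([c[0] == filtered_label for c in loadings.index])
    if not is_filtered.any() or is_filtered.all():
        raise OrientationError("need both filtered and non-filtered columns to orient PC2")
    diff = loadings.loc[is_filtered, "PC2"].mean() - loadings.loc[~is_filtered, "PC2"].mean()
    if diff == 0:
        raise OrientationError("filtered and non-filtered PC2 loadings coincide; orientation undefined")
    if diff < 0:
        scores["PC2"] *= -1
        loadings["PC2"] *= -1
    return PcaResult(scores, loadings, result.variance_fraction.copy(), list(result.columns))


def classify_quadrants(scores: pd.DataFrame) -> pd.Series:
    """Quadrant of each gene from oriented score signs; zeros count as
    positive, so a gene at the origin lands in Quadrant I."""
    pc1 = scores["PC1"].to_numpy()
    pc2 = scores["PC2"].to_numpy()
    q = np.where(
        pc1 >= 0,
        np.where(pc2 >= 0, "I", "IV"),
        np.where(pc2 >= 0, "II", "III"),
    )
    return pd.Series(q, index=scores.index, name="quadrant")


def orient_and_classify(result: PcaResult) -> tuple[PcaResult, pd.Series]:
    oriented = orient(result)
    return oriented, classify_quadrants(oriented.scores)


def euclid_rank(
    scores: pd.DataFrame,
    top_percent: float = 5.0,
    label_percent: float = 0.5,
) -> pd.DataFrame:
    """Rank genes by distance from the origin in the PC1–PC2 plane.

    The top-k% set contains exactly ``ceil(k% × n)`` genes; ties are broken
    lexicographically by gene id for determinism. ``pct`` is the rank
    expressed as a percentage (rank 1 = most extreme).
    """
    if not (0.0 < top_percent < 100.0):
        raise ValueError("top_percent must be in (0, 100)")
    d = np.hypot(scores["PC1"].to_numpy(), scores["PC2"].to_numpy())
    table = pd.DataFrame(
        {"pc1": scores["PC1"], "pc2": scores["PC2"], "dist": d}, index=scores.index
    )
    # (-dist, gene id) order: sort by id first, then stably by descending dist
    table = table.sort_index(kind="mergesort").sort_values("dist", ascending=False, kind="mergesort")
    n = len(table)
    table["rank"] = np.arange(1, n + 1)
    table["pct"] = 100.0 * table["rank"] / n
    k_top = math.ceil(top_percent / 100.0 * n)
    k_label = math.ceil(label_percent / 100.0 * n)
    table["top5"] = table["rank"] <= k_top
    table["top05"] = table["rank"] <= k_label
    return table


@dataclass
class SelectionResult:
    """One replicate's selection: oriented PCA plus the ranked gene table
    (columns pc1, pc2, dist, rank, pct, quadrant, top5, top05)."""

    pca: PcaResult
    table: pd.DataFrame
    water_sample: object = None


def select_replicate(
    gene_table: pd.DataFrame,
    water_sample=None,
    value: str = "f_norm",
    top_percent: float = 5.0,
    label_percent: float = 0.5,
    scale: bool = False,
) -> SelectionResult:
    """Full per-replicate selection: assemble → PCA → orient → rank."""
    matrix = assemble_matrix(gene_table, water_sample=water_sample, value=value)
    oriented, quadrants = orient_and_classify(run_pca(matrix, scale=scale))
    table = euclid_rank(oriented.scores, top_percent=top_percent, label_percent=label_percent)
    table["quadrant"] = quadrants.reindex(table.index)
    return SelectionResult(pca=oriented, table=table, water_sample=water_sample)


@dataclass
class ConsensusResult:
    red: list[str]  # reproducibly enriched (quadrants II/III in every replicate)
    blue: list[str]  # reproducibly depleted (quadrants I/IV in every replicate)
    excluded: list[str]  # top-5% everywhere but with inconsistent quadrant class


def consensus(results: list[SelectionResult]) -> ConsensusResult:
    """Cross-replicate consensus over the top-5% sets.

    A gene must be in every replicate's top-5% and carry the same quadrant
    class (depleted I/IV vs enriched II/III) in all replicates; genes mixing
    classes are excluded and reported.
    """
    if len(results) < 2:
        raise ConfigurationError("consensus needs at least 2 replicates")
    top_sets = [set(r.table.index[r.table["top5"]]) for r in results]
    common = set.intersection(*top_sets)
    red, blue, excluded = [], [], []
    for gene in sorted(common):
        classes = {
            "depleted" if r.table.loc[gene, "quadrant"] in DEPLETED_QUADRANTS else "enriched"
            for r in results
        }
        if len(classes) > 1:
            excluded.append(gene)
        elif classes.pop() == "depleted":
            blue.append(gene)
        else:
            red.append(gene)
    return ConsensusResult(red=red, blue=blue, excluded=excluded)


def plot_biplot(result: SelectionResult, path, gene_labels: bool = True) -> None:
    """Write an SVG/PNG biplot of one replicate: all genes as small dots,
    top-5% as large dots, top-0.5% labelled, loading arrows per column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.scatter(t["pc1"], t["pc2"], s=4, c="0.6", label=None)
    top = t[t["top5"]]
    ax.scatter(top["pc1"], top["pc2"], s=18, c="tab:purple")
    if gene_labels:
        for gene, row in t[t["top05"]].iterrows():
            ax.annotate(str(gene), (row["pc1"], row["pc2"]), fontsize=6)
    scale = float(np.abs(t[["pc1", "pc2"]].to_numpy()).max())
    for col, row in result.pca.loadings.iterrows():
        style = "-" if col[0] == FILTERED else "--"
        ax.plot([0, row["PC1"] * scale], [0, row["PC2"] * scale], style, color="k", lw=0.9)
        ax.annotate(f"{col[0][0]}{col[1]}", (row["PC1"] * scale, row["PC2"] * scale), fontsize=7)
    vf = result.pca.variance_fraction
    ax.set_xlabel(f"PC1 ({vf[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({vf[1] * 100:.1f}%)")
    ax.set_title(f"water sample {result.water_sample}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
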