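"""Self-contained validation studies run against ground truth.

Each function simulates data with the :mod:`barfit.simulate` generator, runs
the corresponding pipeline stage, and measures recovery against the planted
truth or against an independent brute-force oracle. They are used by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import experiment, fitness, select, simulate, tnmap
from .io import iter_fastq


# ------------------------------------------------- end-to-end consensus

def consensus_recovery(seeds, **study_kwargs) -> dict:
    """Median blue/red consensus sensitivity and false-positive count over
    full-design studies (3 water samples × 2 conditions × 3 days × 3 tech
    reps) at the given seeds."""
    rows = [experiment.run_study(int(s), **study_kwargs).metrics() for s in seeds]
    df = pd.DataFrame(rows)
    return {
        "per_seed": rows,
        "blue_sensitivity": float(df["blue_sensitivity"].median()),
        "red_sensitivity": float(df["red_sensitivity"].median()),
        "false_positives": float(df["false_positives"].median()),
    }


# ------------------------------------------------- gene-fitness accuracy

def fitness_accuracy(
    seed: int,
    n_genes: int = 300,
    genome_length: int = 300_000,
    n_insertions: int = 6_000,
    depth: int = 2_000_000,
    abundance_sigma: float = 0.5,
    min_strains: int = 10,
    min_count: int = 50,
) -> dict:
    """RMSE and bias of normalized gene fitness against planted effects.

    Effects spanning [-3, +2] log2 units are planted on a fifth of the
    genes; the comparison is restricted to well-powered genes (>=
    ``min_strains`` insertions whose control counts are >= ``min_count``),
    the regime where the Poisson-weighted estimator is expected to be
    accurate.
    """
    rng = np.random.default_rng(seed)
    annotation, _seq = simulate.simulate_genome(genome_length, n_genes, rng)
    pool, abundances = simulate.simulate_library(
        annotation, n_insertions, coding_fraction=1.0, seed=rng, abundance_sigma=abundance_sigma
    )
    gene_ids = list(annotation.genes["gene_id"])
    n_planted = n_genes // 5
    planted_genes = sorted(
        gene_ids[i] for i in rng.choice(n_genes, size=n_planted, replace=False)
    )
    effects = np.linspace(-3.0, 2.0, n_planted)
    condition, day = select.FILTERED, 2
    effect_map = {g: {(condition, day): float(e)} for g, e in zip(planted_genes, effects)}
    truth = {g: effect_map.get(g, {}).get((condition, day), 0.0) for g in gene_ids}

    expected = simulate.simulate_selection(
        abundances, effect_map, [("control", 0), (condition, day)], pool, annotation
    )
    x = simulate.draw_counts(expected[("control", 0)].to_numpy(), depth, rng)
    y = simulate.draw_counts(expected[(condition, day)].to_numpy(), depth, rng)

    f_s = fitness.strain_fitness(x, y, x.sum(), y.sum())
    v_s = fitness.strain_variance(x, y)
    genes = pool["gene_id"].to_numpy()
    eligible_strain = x >= min_count
    per_gene: dict[str, list] = {}
    for g, f, v, ok in zip(genes, f_s, v_s, eligible_strain):
        if g is not None and ok:
            per_gene.setdefault(g, []).append((f, v))
    order = [g for g in annotation.gene_order() if len(per_gene.get(g, ())) >= min_strains]
    f_raw = np.array([fitness.gene_fitness(*zip(*per_gene[g])) for g in order])
    f_norm = fitness.chromosome_normalize(f_raw)
    err = f_norm - np.array([truth[g] for g in order])
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "bias": float(np.mean(err)),
        "n_genes": len(order),
    }


# --------------------------------------------------- read-QC exactness

def qc_exactness(
    seed: int,
    tmpdir,
    n_genes: int = 100,
    genome_length: int = 60_000,
    n_insertions: int = 300,
    n_clean: int = 3_000,
    defects: dict | None = None,
) -> dict:
    """Seed defective mapping reads and check rejection bookkeeping and
    position recovery are exact.

    Returns the number of rejection-count mismatches against the truth
    sidecar (0 when exact), the fraction of simulated insertions recovered
    at the correct (position, strand), and the count of wrong positions.
    """
    defects = defects or {"bad-length": 50, "low-quality": 50, "no-U2": 50}
    rng = np.random.default_rng(seed)
    annotation, sequence = simulate.simulate_genome(genome_length, n_genes, rng)
    pool, _ab = simulate.simulate_library(annotation, n_insertions, coding_fraction=0.9, seed=rng)
    fastq = str(tmpdir / "mapping.fastq")
    truth = simulate.write_mapping_fastq(
        pool,
        sequence,
        n_clean + sum(defects.values()),
        error_rate=0.0,
        invalid_mix=defects,
        seed=rng,
        path=fastq,
        truth_path=str(tmpdir / "mapping_truth.tsv"),
    )
    built, stats = tnmap.build_pool(iter_fastq(fastq), sequence)
    truth_counts = truth["category"].value_counts().to_dict()
    mismatches = sum(
        int(stats[cat] != truth_counts.get(cat, 0))
        for cat in ("ok", "no-U1", "no-U2", "bad-length", "low-quality")
    )
    merged = built.merge(pool, on="barcode", suffixes=("_est", "_true"))
    correct = (merged["pos_est"] == merged["pos_true"]) & (merged["strand_est"] == merged["strand_true"])
    return {
        "rejection_mismatches": mismatches,
        "recall": float(correct.sum() / len(pool)),
        "wrong_positions": int((~correct).sum()),
        "stats": stats,
    }


# --------------------------------------------------- brute-force oracles

def pca_oracle(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the column covariance: returns (scores,
    loadings, variance fractions), PCs ordered by decreasing eigenvalue.
    Independent of the SVD route used by :func:`barfit.select.run_pca`."""
    X = matrix - matrix.mean(axis=0)
    cov = X.T @ X / (X.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    total = np.trace(cov)
    return X @ v, v, w / total


def pca_oracle_deviation(seed: int, n_matrices: int = 100, shape=(50, 6)) -> float:
    """Max |difference| between pipeline PCA and the eigen oracle (scores
    and loadings, sign-aligned) over random matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        X = rng.normal(size=shape)
        df = pd.DataFrame(
            X,
            index=[f"g{i:03d}" for i in range(shape[0])],
            columns=pd.MultiIndex.from_product([["filtered", "non-filtered"], [2, 4, 8]]),
        )
        res = select.run_pca(df)
        o_scores, o_load, _vf = pca_oracle(X)
        for k in range(2):
            s = res.scores.iloc[:, k].to_numpy()
            o = o_scores[:, k]
            sign = 1.0 if np.dot(s, o) >= 0 else -1.0
            worst = max(worst, float(np.max(np.abs(s - sign * o))))
            worst = max(
                worst,
                float(np.max(np.abs(res.loadings.iloc[:, k].to_numpy() - sign * o_load[:, k]))),
            )
    return worst


def running_median_oracle(values: np.ndarray, window: int) -> np.ndarray:
    """Naive O(n·w) centered circular running median."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    h = window // 2
    out = np.empty(n)
    for i in range(n):
        idx = (np.arange(i - h, i + h + 1)) % n
        out[i] = np.median(v[idx])
    return out


def running_median_oracle_deviation(seed: int, sizes=(5, 251, 1000, 5000), window: int = 251) -> float:
    """Max |difference| between the pipeline running median and the naive
    oracle on random vectors (window shrunk for short vectors)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in sizes:
        v = rng.normal(size=n)
        w = min(window, n if n % 2 == 1 else n - 1)
        worst = max(worst, float(np.max(np.abs(fitness.running_median(v, w) - running_median_oracle(v, w)))))
    return worst
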