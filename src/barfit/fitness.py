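"""Strain and gene fitness estimation.

Strain fitness is the log2 ratio of a barcode's frequency between a
treatment sample and its Day-0 control, with a pseudocount keeping zero
counts finite:

    f_s = log2((y + eps) / Y) - log2((x + eps) / X)

where x, y are the barcode's counts and X, Y the sample totals. The
associated variance proxy is the delta-method (Poisson) variance of a log2
ratio of counts:

    V_s = (1/(x + eps) + 1/(y + eps)) / (ln 2)^2

Gene fitness is the inverse-variance-weighted mean of the strain fitnesses
of the insertions within the gene's coding region. Per sample, gene fitness
is then normalized along the chromosome — a centered running median
(window 251, circular wrap) removes position-dependent bias such as the
ori→ter copy-number gradient, and the distribution mode is subtracted so
that the bulk of (neutral) genes sits at zero. Technical replicates are
averaged last.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import ConfigurationError

_LN2_SQ = np.log(2.0) ** 2

DEFAULT_WINDOW = 251
DEFAULT_PSEUDOCOUNT = 1.0


# ----------------------------------------------------------- strain level

def strain_fitness(x, y, X, Y, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Normalized log2 count ratio (treatment y/Y vs control x/X).

    Accepts scalars or arrays. ``pseudocount=0`` evaluates the raw formula
    (finite only for strictly positive counts).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(X <= 0) or np.any(Y <= 0):
        raise ValueError("sample totals must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    return np.log2((y + pseudocount) / Y) - np.log2((x + pseudocount) / X)


def strain_variance(x, y, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Poisson (delta-method) variance of the log2 ratio; symmetric in x, y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (1.0 / (x + pseudocount) + 1.0 / (y + pseudocount)) / _LN2_SQ


def gene_fitness(fitnesses, variances) -> float:
    """Inverse-variance-weighted mean of one gene's strain fitnesses."""
    f = np.asarray(fitnesses, dtype=float)
    v = np.asarray(variances, dtype=float)
    if f.size == 0:
        raise ValueError("gene_fitness requires at least one strain")
    w = 1.0 / v
    return float(np.sum(w * f) / np.sum(w))


# ------------------------------------------------------- chromosome level

def running_median(values, window: int) -> np.ndarray:
    """Centered running median with circular wrap (the chromosome is circular)."""
    v = np.asarray(values, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    return median_filter(v, size=window, mode="wrap")


def estimate_mode(values, fallback_width: float = 0.05) -> float:
    """Histogram-mode estimate: center of the fullest Freedman–Diaconis bin.

    Falls back to fixed 0.05 log2-unit bins when the FD width degenerates
    (zero IQR or too few points).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("cannot estimate the mode of an empty vector")
    span = float(v.max() - v.min())
    if span == 0.0:
        return float(v[0])
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    width = 2.0 * iqr / v.size ** (1.0 / 3.0)
    if not np.isfinite(width) or width <= 0:
        width = fallback_width
    nbins = int(np.ceil(span / width))
    nbins = max(1, min(nbins, 10_000))
    hist, edges = np.histogram(v, bins=nbins)
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2.0)


def chromosome_normalize(values, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Subtract the circular running median, then the mode of the residuals.

    ``values`` must already be ordered by chromosomal gene midpoint. When
    fewer genes than the window are available the window shrinks to the
    largest odd size that fits (with a warning).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v.copy()
    w = window
    if w > v.size:
        w = v.size if v.size % 2 == 1 else v.size - 1
        w = max(w, 1)
        warnings.warn(
            f"window {window} larger than the {v.size} genes available; shrinking to {w}",
            stacklevel=2,
        )
    step1 = v - running_median(v, w)
    return step1 - estimate_mode(step1)


# --------------------------------------------------------- whole pipeline

def _control_lookup(sheet: pd.DataFrame) -> dict[tuple, str]:
    controls = sheet[sheet["day"] == 0]
    lookup: dict[tuple, str] = {}
    for _, row in controls.iterrows():
        key = (row["water_sample"], row["tech_rep"])
        if key in lookup:
            raise ConfigurationError(f"duplicate Day-0 control for lineage {key}")
        lookup[key] = row["sample_id"]
    return lookup


def strain_fitness_table(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain fitness and variance for every treatment sample.

    Each treatment sample (day > 0) is compared against the Day-0 control of
    the same (water sample, technical replicate) lineage. Returns two wide
    DataFrames (barcode × treatment sample): fitness and variance.
    """
    controls = _control_lookup(sample_sheet)
    f_cols: dict[str, np.ndarray] = {}
    v_cols: dict[str, np.ndarray] = {}
    for _, row in sample_sheet[sample_sheet["day"] != 0].iterrows():
        key = (row["water_sample"], row["tech_rep"])
        if key not in controls:
            raise ConfigurationError(f"no Day-0 control for lineage {key}")
        sid = row["sample_id"]
        x = counts[controls[key]].to_numpy()
        y = counts[sid].to_numpy()
        f_cols[sid] = strain_fitness(x, y, x.sum(), y.sum(), pseudocount)
        v_cols[sid] = strain_variance(x, y, pseudocount)
    f = pd.DataFrame(f_cols, index=counts.index)
    v = pd.DataFrame(v_cols, index=counts.index)
    return f, v


def gene_fitness_table(
    strain_f: pd.DataFrame,
    strain_v: pd.DataFrame,
    pool: pd.DataFrame,
    annotation,
    sample_sheet: pd.DataFrame,
    min_strains: int = 1,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Aggregate strain fitness to genes and normalize along the chromosome.

    Only gene-assigned strains contribute. Output is a long DataFrame with
    columns ``gene, water_sample, condition, day, tech_rep, f_raw, f_norm,
    n_strains``; genes with fewer than ``min_strains`` insertions are
    absent (not NaN-filled).
    """
    pool = pool.set_index("barcode").loc[strain_f.index]
    gene_arr = pool["gene_id"].to_numpy()
    has_gene = np.array([g is not None and g == g for g in gene_arr])
    codes_all = pd.Categorical(gene_arr[has_gene])
    gene_ids = np.asarray(codes_all.categories)
    codes = codes_all.codes
    n_strains = np.bincount(codes, minlength=len(gene_ids))

    present = set(gene_ids)
    order = [g for g in annotation.gene_order() if g in present]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    order_idx = np.array([gene_pos[g] for g in order])
    eligible = n_strains[order_idx] >= min_strains
    order = [g for g, ok in zip(order, eligible) if ok]
    order_idx = order_idx[eligible]

    meta = sample_sheet.set_index("sample_id")
    frames = []
    for sid in strain_f.columns:
        f = strain_f[sid].to_numpy()[has_gene]
        w = 1.0 / strain_v[sid].to_numpy()[has_gene]
        num = np.bincount(codes, weights=w * f, minlength=len(gene_ids))
        den = np.bincount(codes, weights=w, minlength=len(gene_ids))
        f_raw = (num / den)[order_idx]
        f_norm = chromosome_normalize(f_raw, window=window)
        row = meta.loc[sid]
        frames.append(
            pd.DataFrame(
                {
                    "gene": order,
                    "water_sample": row["water_sample"],
                    "condition": row["condition"],
                    "day": row["day"],
                    "tech_rep": row["tech_rep"],
                    "f_raw": f_raw,
                    "f_norm": f_norm,
                    "n_strains": n_strains[order_idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def average_technical_replicates(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean over technical replicates per (water sample,
    condition, day). Genes missing in some replicates are averaged over the
    replicates where they are present and flagged ``partial``.
    """
    keys = ["gene", "water_sample", "condition", "day"]
    grouped = gene_table.groupby(keys, sort=False).agg(
        f_raw=("f_raw", "mean"),
        f_norm=("f_norm", "mean"),
        n_strains=("n_strains", "first"),
        n_reps=("tech_rep", "nunique"),
    )
    expected = (
        gene_table.groupby(["water_sample", "condition", "day"])["tech_rep"].nunique().rename("expected_reps")
    )
    out = grouped.reset_index().merge(expected.reset_index(), on=["water_sample", "condition", "day"])
    out["partial"] = out["n_reps"] < out["expected_reps"]
    if out["partial"].any():
        warnings.warn(
            f"{int(out['partial'].sum())} gene×sample cells averaged over a subset of replicates",
            stacklevel=2,
        )
    return out.drop(columns="expected_reps")


def fitness_pipeline(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pool: pd.DataFrame,
    annotation,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_strains: int = 1,
    window: int = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts → strain fitness → normalized gene fitness → replicate means.

    Returns (strain fitness wide, per-replicate gene table, replicate-averaged
    gene table).
    """
    strain_f, strain_v = strain_fitness_table(counts, sample_sheet, pseudocount)
    per_rep = gene_fitness_table(
        strain_f, strain_v, pool, annotation, sample_sheet, min_strains=min_strains, window=window
    )
    averaged = average_technical_replicates(per_rep)
    return strain_f, per_rep, averaged
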