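"""Expression-matrix transforms and the CN-dosage analysis.

An :class:`ExpressionMatrix` bundles a genes x samples log2 value frame,
per-gene coordinates and a per-sample batch label (e.g. FFPE vs fresh
frozen).  The dosage analysis asks whether losing or gaining a chromosome
moves the mean expression of its genes — at whole-chromosome scale via
per-tumor Pearson correlation of dominant CN with chromosome mean
expression, and at sub-chromosomal scale via per-segment means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .loh import Karyotype


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame      # genes x samples, log2 scale
    gene_info: pd.DataFrame   # indexed by gene_id: chrom, start, end
    batches: pd.Series        # sample -> batch label

    def __post_init__(self) -> None:
        if not self.values.index.isin(self.gene_info.index).all():
            raise ValueError("every gene in the matrix needs coordinates")
        if not self.values.columns.isin(self.batches.index).all():
            raise ValueError("every sample needs a batch label")


def batch_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove additive batch effects by within-batch gene mean-centering.

    For each gene and each batch, the mean across that batch's samples is
    subtracted, so per-gene per-batch means become exactly zero.  Requires
    >= 2 samples per batch (a singleton batch would be zeroed outright).
    """
    sizes = matrix.batches.value_counts()
    if (sizes < 2).any():
        bad = list(sizes.index[sizes < 2])
        raise ValueError(f"batches with a single sample cannot be centered: {bad}")
    vals = matrix.values.copy()
    for batch in sizes.index:
        cols = matrix.batches.index[matrix.batches == batch]
        cols = [c for c in cols if c in vals.columns]
        vals[cols] = vals[cols].sub(vals[cols].mean(axis=1), axis=0)
    return replace(matrix, values=vals)


def zscore(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """Gene-wise Z-score across the cohort (sample SD, ddof=1).

    Zero-variance genes get Z = 0 and are flagged in the returned boolean
    Series.  Requires >= 3 samples.
    """
    vals = matrix.values
    if vals.shape[1] < 3:
        raise ValueError("Z-scoring needs >= 3 samples")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    flat = sd == 0
    sd_safe = sd.mask(flat, 1.0)
    z = vals.sub(mean, axis=0).div(sd_safe, axis=0)
    z[flat] = 0.0
    return replace(matrix, values=z), flat


def chromosome_mean_expression(
    matrix: ExpressionMatrix, min_genes: int = 5
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample mean expression of each chromosome's genes.

    Genes are assigned to chromosomes by their annotated coordinates.
    Returns (samples x chromosomes DataFrame, per-chromosome gene counts);
    chromosomes with fewer than ``min_genes`` genes are kept but flagged by
    the count series (callers may mask them).
    """
    info = matrix.gene_info.loc[matrix.values.index]
    counts = info.groupby("chrom").size()
    means = {}
    for chrom, genes in info.groupby("chrom").groups.items():
        means[chrom] = matrix.values.loc[genes].mean(axis=0)
    if not means:
        raise ValueError("no genes with coordinates")
    out = pd.DataFrame(means)
    few = counts[counts < min_genes]
    if len(few):
        warnings.warn(f"chromosomes with < {min_genes} genes: {list(few.index)}",
                      stacklevel=2)
    return out, counts


def cn_expression_correlation(
    karyotype: Karyotype, chrom_means: pd.Series
) -> float:
    """Pearson r between per-chromosome dominant CN and mean expression.

    Returns NaN when CN is constant across chromosomes (euploid tumor;
    the correlation is undefined and such tumors are excluded from
    cohort histograms rather than recorded as r = 0) or when fewer than
    three chromosomes have both values.
    """
    calls = karyotype.calls.set_index("chrom")["dominant_cn"]
    common = calls.index.intersection(chrom_means.index)
    if len(common) < 3:
        return float("nan")
    cn = calls.loc[common].to_numpy(dtype=float)
    expr = chrom_means.loc[common].to_numpy(dtype=float)
    if np.ptp(cn) == 0 or np.ptp(expr) == 0:
        return float("nan")
    return float(stats.pearsonr(cn, expr).statistic)


def cohort_cn_expression_correlations(
    karyotypes: list[Karyotype], chrom_means: pd.DataFrame
) -> pd.Series:
    """Per-tumor CN-expression Pearson r; euploid tumors come back NaN."""
    out = {}
    for k in karyotypes:
        if k.tumor_id in chrom_means.index:
            out[k.tumor_id] = cn_expression_correlation(k, chrom_means.loc[k.tumor_id])
    return pd.Series(out, dtype=float)


def segment_mean_expression(
    segments: pd.DataFrame, matrix: ExpressionMatrix, sample: str,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Mean expression of the genes whose midpoint falls in each segment.

    Adds ``n_genes, mean_expr, few_genes`` columns; segments with fewer
    than ``min_genes`` genes are flagged and their mean left as NaN.
    """
    info = matrix.gene_info.loc[matrix.values.index]
    mid = ((info["start"] + info["end"]) // 2)
    vals = matrix.values[sample]
    out = segments.copy()
    n_genes, means = [], []
    for _, seg in out.iterrows():
        sel = (info["chrom"] == seg["chrom"]) & (mid > seg["start"]) & (mid <= seg["end"])
        n = int(sel.sum())
        n_genes.append(n)
        means.append(float(vals[sel.to_numpy()].mean()) if n >= min_genes else np.nan)
    out["n_genes"] = n_genes
    out["mean_expr"] = means
    out["few_genes"] = out["n_genes"] < min_genes
    return out


def compare_loss_vs_intact(
    chrom_means: pd.DataFrame,
    karyotypes: list[Karyotype],
    chrom: str,
    min_group: int = 3,
    exact_max_n: int = 8,
) -> dict:
    """Mann-Whitney U comparison of a chromosome's mean expression:
    tumors that lost the chromosome (dominant CN < 2) vs tumors with it
    intact (dominant CN = 2, including copy-neutral LoH, which leaves
    dosage unchanged).

    Uses the exact U distribution when the smaller group has at most
    ``exact_max_n`` tumors and no ties, otherwise the tie-corrected normal
    approximation.  Returns the U statistic, two-sided p, group means and
    direction.
    """
    loss_ids, intact_ids = [], []
    for k in karyotypes:
        call = k.calls.loc[k.calls["chrom"] == chrom]
        if call.empty or k.tumor_id not in chrom_means.index:
            continue
        cn = int(call["dominant_cn"].iloc[0])
        if cn < 2:
            loss_ids.append(k.tumor_id)
        elif cn == 2:
            intact_ids.append(k.tumor_id)
    x = chrom_means.loc[loss_ids, chrom].dropna()
    y = chrom_means.loc[intact_ids, chrom].dropna()
    if len(x) < min_group or len(y) < min_group:
        raise ValueError(
            f"need >= {min_group} tumors per group (got {len(x)} loss, {len(y)} intact)")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "n_loss": int(len(x)),
        "n_intact": int(len(y)),
        "mean_loss": float(x.mean()),
        "mean_intact": float(y.mean()),
        "direction": "loss_lower" if x.mean() < y.mean() else "loss_higher",
        "method": method,
    }
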