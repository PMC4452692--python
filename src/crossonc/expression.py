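"""Copy-number / expression integration and group comparisons.

Expression is classified low/normal/high per gene against an interval
built from the samples that are copy-neutral (diploid) for that gene.
The interval is a Student-t *prediction* interval for one new
observation on the log2(FPKM + 1) scale:

    mean +- t_{1 - alpha/2, n-1} * s * sqrt(1 + 1/n)

A plain confidence interval for the mean would flag far more than
``alpha`` of diploid samples as outliers; the prediction interval
calibrates the outlier rate to ``alpha``.  Diploid reference samples are
classified against the leave-one-out interval to avoid self-inclusion
bias.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GeneCnaMatrix


def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(FPKM + pseudocount); the scale used for all statistics here."""
    if (matrix.values < 0).any():
        raise ValueError("expression values must be >= 0")
    return np.log2(matrix + pseudocount)


def filter_expressed(
    matrix: pd.DataFrame, min_fpkm: float = 1.0, min_samples: int = 1
) -> pd.DataFrame:
    """Keep genes with FPKM >= min_fpkm in at least min_samples samples (inclusive)."""
    keep = (matrix >= min_fpkm).sum(axis=1) >= min_samples
    return matrix.loc[keep]


def prediction_interval(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Student-t prediction interval for one new observation.

    Zero-variance references give a degenerate (point) interval.
    """
    values = np.asarray(values, float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 reference values")
    m = float(np.mean(values))
    s = float(np.std(values, ddof=1))
    if s == 0.0:
        return (m, m)
    half = stats.t.ppf(1 - alpha / 2, n - 1) * s * np.sqrt(1 + 1 / n)
    return (m - half, m + half)


def classify_value(value: float, lo: float, hi: float) -> str:
    if value > hi:
        return "high"
    if value < lo:
        return "low"
    return "normal"


def classify_expression(
    matrix: pd.DataFrame,
    gene_cna: GeneCnaMatrix,
    alpha: float = 0.05,
    min_diploid: int = 3,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per gene x sample low/normal/high calls against the diploid reference.

    Returns a long frame with columns gene_id, sample_id, level, lo, hi,
    n_ref.  Genes with fewer than ``min_diploid`` diploid samples are
    ``unclassifiable``; zero-variance references yield a degenerate
    interval where only exact equality is "normal" (flagged via lo == hi).
    """
    common_genes = matrix.index.intersection(gene_cna.gene_ids)
    common_samples = matrix.columns.intersection(gene_cna.sample_ids)
    y = log_transform(matrix.loc[common_genes, common_samples], pseudocount)
    status = gene_cna.status.loc[common_genes, common_samples]
    rows = []
    for g in common_genes:
        vals = y.loc[g]
        diploid = status.loc[g] == 0
        ref_ids = list(common_samples[diploid])
        n_ref = len(ref_ids)
        if n_ref < min_diploid:
            for s in common_samples:
                rows.append((g, s, "unclassifiable", np.nan, np.nan, n_ref))
            continue
        ref_vals = vals[ref_ids].to_numpy(float)
        lo_all, hi_all = prediction_interval(ref_vals, alpha)
        for s in common_samples:
            v = float(vals[s])
            if s in ref_ids:
                loo = vals[[r for r in ref_ids if r != s]].to_numpy(float)
                lo, hi = prediction_interval(loo, alpha)
                rows.append((g, s, classify_value(v, lo, hi), lo, hi, n_ref - 1))
            else:
                rows.append((g, s, classify_value(v, lo_all, hi_all), lo_all, hi_all, n_ref))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "level", "lo", "hi", "n_ref"])


_LEVELS = ["low", "normal", "high"]
_CNA_GROUPS = ["Del", "unchanged", "Amp"]


def concordance_table(calls: pd.DataFrame, gene_cna: GeneCnaMatrix) -> pd.DataFrame:
    """3x3 table of percentages: CNA group (columns) x expression level (rows).

    Each (gene, sample) pair contributes once; ``unclassifiable`` calls
    are dropped.  Every populated column sums to 100%.
    """
    usable = calls[calls["level"].isin(_LEVELS)]
    counts = pd.DataFrame(0, index=_LEVELS, columns=_CNA_GROUPS, dtype=float)
    status = gene_cna.status
    for g, s, level in usable[["gene_id", "sample_id", "level"]].itertuples(index=False):
        st = int(status.loc[g, s])
        group = _CNA_GROUPS[st + 1]
        counts.loc[level, group] += 1
    totals = counts.sum(axis=0)
    pct = counts.copy()
    for col in pct.columns:
        pct[col] = 100.0 * counts[col] / totals[col] if totals[col] > 0 else 0.0
    return pct


def differential_expression_ttest(
    matrix: pd.DataFrame,
    tumor_ids: list[str],
    normal_ids: list[str],
    fdr: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Welch t-test per gene on log2(FPKM+1) between two sample groups.

    Returns per-gene t, p, q (Benjamini-Hochberg), direction (sign of
    tumor minus normal mean), and the significance flag at ``fdr``.
    """
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("need >= 2 samples per group")
    y = log_transform(matrix, pseudocount)
    a = y[tumor_ids].to_numpy(float)
    b = y[normal_ids].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    diff = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "direction": np.sign(diff).astype(int),
            "log2_fc": diff,
            "significant": q <= fdr,
        },
        index=matrix.index,
    )


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f: float
    df1: int
    df2: int
    p_value: float


def hotelling_concordance(group_a: np.ndarray, group_b: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling T-squared test on per-gene feature vectors.

    Each row of ``group_a``/``group_b`` is one gene's feature vector —
    here, its (mean log2 copy ratio, mean log2 expression) pair.  The
    statistic is converted to an F with ``T2 * (n1+n2-p-1) /
    (p*(n1+n2-2))`` on (p, n1+n2-p-1) degrees of freedom.
    """
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with matching feature dimension")
    n1, p = a.shape
    n2 = b.shape[0]
    if n1 < 3 or n2 < 3:
        raise ValueError("need >= 3 genes per group")
    d = a.mean(axis=0) - b.mean(axis=0)
    s1 = np.cov(a, rowvar=False)
    s2 = np.cov(b, rowvar=False)
    s_pool = np.atleast_2d(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if np.linalg.cond(s_pool) > 1e12:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; jitter the features or drop a dimension"
        )
    t2 = float((n1 * n2) / (n1 + n2) * d @ np.linalg.solve(s_pool, d))
    df1, df2 = p, n1 + n2 - p - 1
    f = t2 * df2 / (p * (n1 + n2 - 2))
    p_value = float(stats.f.sf(f, df1, df2))
    return HotellingResult(t2=t2, f=float(f), df1=df1, df2=df2, p_value=p_value)
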