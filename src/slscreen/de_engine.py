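"""Differential expression of genes and miRNAs, tumor vs normal.

A deliberately simple, fully documented estimator producing the summary
fields the downstream screens consume (baseMean, log2FC, pvalue, padj,
status): median-of-ratios size factors, a Welch t-test on
log2(normalized + 1), and Benjamini-Hochberg adjustment within each
cancer type.  It does not attempt negative-binomial GLM shrinkage; see
docs/methods.md for the rationale and consequences.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Pseudo-count added before log2 ratios so zero counts stay finite.
PSEUDOCOUNT = 1.0

DE_COLUMNS = ["gene", "baseMean", "log2FC", "pvalue", "padj", "status"]


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios sample scale factors.

    factor_j = median over reference genes g of count_gj / geomean_g, where
    the reference genes are those with strictly positive counts in every
    sample.  With ``pseudo_reference=True`` the geometric mean is instead
    taken over each gene's positive counts only, rescuing sparse matrices
    where no gene is positive everywhere.
    """
    x = counts.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError("counts must be a nonempty genes x samples matrix")
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
        n_pos = np.sum(x > 0, axis=1)
        ref_mask = n_pos > 0
        geo = np.exp(np.nansum(logx, axis=1)[ref_mask] / n_pos[ref_mask])
        ratios = x[ref_mask] / geo[:, None]
        ratios = np.where(x[ref_mask] > 0, ratios, np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        all_pos = np.all(x > 0, axis=1)
        if not all_pos.any():
            raise ValueError(
                "no gene has positive counts in every sample; "
                "re-run with pseudo_reference=True"
            )
        ref = x[all_pos]
        geo = np.exp(np.mean(np.log(ref), axis=1))
        factors = np.median(ref / geo[:, None], axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("degenerate size factors; check the count matrix")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.DataFrame:
    return counts / size_factors(counts, pseudo_reference=pseudo_reference)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    counts: pd.DataFrame,
    labels: pd.Series,
    fc_cut: float = 1.5,
    alpha: float = 0.05,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression for one cancer type.

    Parameters
    ----------
    counts : genes x samples raw count matrix.
    labels : per-sample condition, values "tumor" / "normal".
    fc_cut, alpha : thresholds defining the up/down/normal status call:
        up iff log2FC > fc_cut and padj < alpha; down symmetric.

    Returns a DataFrame with columns gene, baseMean, log2FC, pvalue, padj,
    status.  log2FC = log2((mean normalized tumor + 1) / (mean normalized
    normal + 1)); the p-value is a two-sided Welch t-test on
    log2(normalized + 1).  Genes with no variance (e.g. all-zero) get
    p = 1.
    """
    labels = pd.Series(labels).reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a condition label")
    bad = set(labels.unique()) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"labels must be 'tumor'/'normal'; got {sorted(bad)}")
    tumor = labels.index[labels == "tumor"]
    normal = labels.index[labels == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >= 2 samples per condition (got {len(tumor)} tumor, {len(normal)} normal)"
        )

    norm = counts / size_factors(counts, pseudo_reference=pseudo_reference)
    base_mean = norm.mean(axis=1).to_numpy()
    mean_t = norm[tumor].mean(axis=1).to_numpy()
    mean_n = norm[normal].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_t + PSEUDOCOUNT) - np.log2(mean_n + PSEUDOCOUNT)

    logx = np.log2(norm.to_numpy() + 1.0)
    xt = logx[:, counts.columns.get_indexer(tumor)]
    xn = logx[:, counts.columns.get_indexer(normal)]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    padj = bh_adjust(pvals)
    status = np.where(
        (log2fc > fc_cut) & (padj < alpha),
        "up",
        np.where((log2fc < -fc_cut) & (padj < alpha), "down", "normal"),
    )
    return pd.DataFrame(
        {
            "gene": counts.index,
            "baseMean": base_mean,
            "log2FC": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "status": status,
        }
    )
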