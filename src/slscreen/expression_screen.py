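"""Expression-level dysregulation cascade.

Aggregates per-cancer differential-expression status into a gene x cancer
dysregulation matrix, screens genes dysregulated in many cancer types
(strictly more than 10 by default) and pairs whose both members pass,
derives per-sample abnormality calls for AA / AN / NN patient grouping,
and provides the directional z score (up - down) / count used to
summarize expression trends of an annotated gene set.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._types import GenePair
from .de_engine import size_factors

STATUSES = ("up", "down", "normal")


def build_dysregulation_matrix(de_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-cancer DE tables into a genes x cancers status matrix.

    *de_results* maps cancer code -> DE table with columns gene, status.
    Genes absent from a cancer's table are "normal" there.  Conflicting
    duplicate (gene, cancer) entries raise.
    """
    columns = {}
    for cancer, df in de_results.items():
        dup = df[df["gene"].duplicated(keep=False)]
        if len(dup) and dup.groupby("gene")["status"].nunique().max() > 1:
            raise ValueError(f"conflicting duplicate statuses in cancer {cancer}")
        columns[cancer] = df.drop_duplicates("gene").set_index("gene")["status"]
    matrix = pd.DataFrame(columns).fillna("normal")
    matrix = matrix.sort_index().sort_index(axis=1)
    return matrix


def n_dysregulated(matrix: pd.DataFrame) -> pd.Series:
    """Per gene, the number of cancer types with status != normal."""
    return (matrix != "normal").sum(axis=1).rename("n_dysregulated")


def select_dysregulated_genes(matrix: pd.DataFrame, min_cancers: int = 11) -> list[str]:
    """Genes dysregulated in at least *min_cancers* cancer types
    (default 11, i.e. strictly more than 10)."""
    counts = n_dysregulated(matrix)
    return sorted(counts.index[counts >= min_cancers])


def select_dysregulated_pairs(catalog: list[GenePair], selected_genes) -> list[GenePair]:
    """Pairs with BOTH members in the selected gene list."""
    selected = set(selected_genes)
    return [p for p in catalog if p.gene_a in selected and p.gene_b in selected]


def direction_consistency(matrix: pd.DataFrame) -> pd.Series:
    """Per gene, the fraction of its dysregulated cancers sharing the
    majority direction (descriptive; not a filter).  Genes dysregulated
    nowhere get NaN."""
    out = {}
    for gene, row in matrix.iterrows():
        ups = int((row == "up").sum())
        downs = int((row == "down").sum())
        total = ups + downs
        out[gene] = max(ups, downs) / total if total else np.nan
    return pd.Series(out, name="direction_consistency")


def sample_abnormality(
    counts: pd.DataFrame,
    normal_samples,
    z_cut: float = 1.96,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Per-sample per-gene abnormal-expression flags.

    Counts are size-factor normalized and log2(x + 1) transformed; a value
    is abnormal iff |x - mu_normal| / sigma_normal > z_cut, where mu/sigma
    are estimated from the normal samples.  Genes with sigma_normal = 0 are
    never abnormal.  At least 3 normal samples are required.
    """
    normal_samples = [s for s in normal_samples if s in counts.columns]
    if len(normal_samples) < 3:
        raise ValueError("need >= 3 normal samples to estimate the reference distribution")
    norm = counts / size_factors(counts, pseudo_reference=pseudo_reference)
    logx = np.log2(norm.to_numpy(dtype=float) + 1.0)
    logx = pd.DataFrame(logx, index=counts.index, columns=counts.columns)
    ref = logx[normal_samples]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    z = logx.sub(mu, axis=0).abs().div(sd.replace(0.0, np.inf), axis=0)
    return z > z_cut


def assign_expression_groups(pair: GenePair, abnormal_flags: pd.DataFrame) -> pd.Series:
    """Partition samples into AA / AN / NN for one pair from per-gene
    abnormality flags (genes x samples boolean matrix)."""
    for g in pair.key:
        if g not in abnormal_flags.index:
            raise ValueError(f"no abnormality flags for gene {g}")
    a = abnormal_flags.loc[pair.gene_a]
    b = abnormal_flags.loc[pair.gene_b]
    out = np.where(a & b, "AA", np.where(~a & ~b, "NN", "AN"))
    return pd.Series(out, index=abnormal_flags.columns, name="group")


def go_zscore(up: int, down: int, count: int) -> float:
    """Directional z score (up - down) / count for a gene set's expression
    pattern; +1 all up, -1 all down, 0 balanced."""
    if count <= 0:
        raise ValueError("count must be positive")
    if up < 0 or down < 0 or up + down > count:
        raise ValueError("need up, down >= 0 and up + down <= count")
    return (up - down) / count
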