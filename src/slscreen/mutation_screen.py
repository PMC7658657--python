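"""Mutation-level screening of candidate synthetic-lethal pairs.

Computes per-gene per-cancer mutation frequencies from MAF-style call
tables, retains pairs in which both genes are recurrently mutated
(frequency > 2% of the cohort in at least five cancer types by default),
partitions patients into MM / MW / WW groups for each pair, summarizes
variant-class composition, and tests drug-response differences between
groups.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._types import VARIANT_CLASSES, GenePair
from .de_engine import bh_adjust

log = logging.getLogger(__name__)

MAF_COLUMNS = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "cancer_type"]


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-subset TSV into the internal call table
    (sample, gene, cancer, variant_class)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing MAF columns {sorted(missing)}")
    return pd.DataFrame(
        {
            "sample": df["Tumor_Sample_Barcode"],
            "gene": df["Hugo_Symbol"],
            "cancer": df["cancer_type"],
            "variant_class": df["Variant_Classification"],
        }
    )


def mutation_frequency(calls: pd.DataFrame, cohort_sizes: dict[str, int]) -> pd.DataFrame:
    """Per-(gene, cancer) mutation frequency.

    frequency = |distinct mutated samples| / cohort size; repeated calls on
    the same (sample, gene) count once.  Denominators are the full cohort
    sizes supplied by the caller, not the number of samples present in the
    call table.
    """
    for c, n in cohort_sizes.items():
        if n <= 0:
            raise ValueError(f"cohort size for {c} must be positive")
    unknown = set(calls["cancer"].unique()) - set(cohort_sizes)
    if unknown:
        raise ValueError(f"calls reference cancer(s) without cohort size: {sorted(unknown)}")
    dedup = calls.drop_duplicates(subset=["sample", "gene", "cancer"])
    counts = dedup.groupby(["gene", "cancer"]).size()
    freq = counts / pd.Series(cohort_sizes).reindex(
        counts.index.get_level_values("cancer")
    ).to_numpy()
    return freq.rename("frequency").reset_index()


def _freq_lookup(freqs: pd.DataFrame) -> dict[tuple[str, str], float]:
    return {
        (g, c): f
        for g, c, f in freqs[["gene", "cancer", "frequency"]].itertuples(index=False)
    }


def select_mutated_pairs(
    catalog: list[GenePair],
    freqs: pd.DataFrame,
    min_freq: float = 0.02,
    min_cancers: int = 5,
) -> pd.DataFrame:
    """Pairs whose BOTH genes exceed *min_freq* mutation frequency in at
    least *min_cancers* common cancer types.

    Returns one row per retained pair with the semicolon-joined list of
    qualifying cancers.
    """
    lut = _freq_lookup(freqs)
    cancers = sorted(freqs["cancer"].unique())
    rows = []
    for p in catalog:
        qualifying = [
            c
            for c in cancers
            if lut.get((p.gene_a, c), 0.0) > min_freq and lut.get((p.gene_b, c), 0.0) > min_freq
        ]
        if len(qualifying) >= min_cancers:
            rows.append((p.gene_a, p.gene_b, len(qualifying), ";".join(qualifying)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_qualifying", "qualifying_cancers"])


def assign_mutation_groups(
    pair: GenePair, calls: pd.DataFrame, cancer: str, cohort: list[str]
) -> pd.Series:
    """Partition a cancer cohort into MM / MW / WW for one pair.

    MM: both genes mutated in the sample; WW: neither; MW: exactly one.
    Every cohort sample receives exactly one group.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    sub = calls[(calls["cancer"] == cancer) & (calls["gene"].isin([pair.gene_a, pair.gene_b]))]
    mut_a = set(sub.loc[sub["gene"] == pair.gene_a, "sample"])
    mut_b = set(sub.loc[sub["gene"] == pair.gene_b, "sample"])
    out = {}
    for s in cohort:
        a, b = s in mut_a, s in mut_b
        out[s] = "MM" if (a and b) else ("WW" if not (a or b) else "MW")
    return pd.Series(out, name="group")


def mutation_type_composition(pair: GenePair, calls: pd.DataFrame) -> pd.Series:
    """Variant-class proportions over all calls touching either gene of the
    pair; ordered (missense, nonsense, frameshift, splice, other)."""
    sub = calls[calls["gene"].isin([pair.gene_a, pair.gene_b])]
    if len(sub) == 0:
        raise ValueError(f"no calls for pair {pair.key}")
    props = (
        sub["variant_class"].value_counts(normalize=True).reindex(VARIANT_CLASSES, fill_value=0.0)
    )
    props.name = "proportion"
    return props


def drug_association(
    groups: pd.Series,
    drug_matrix: pd.DataFrame,
    group_pair: tuple[str, str] = ("MM", "WW"),
    effect_cut: float = 0.10,
    alpha: float = 0.05,
    fdr_cut: float = 0.10,
    min_group: int = 3,
) -> pd.DataFrame:
    """Between-group drug-response differences for one pair contrast.

    For each drug, effect = mean(group1) - mean(group2) of min-max
    normalized responses in [0, 1]; p from a two-sided Mann-Whitney test.
    A drug is significant iff |effect| > effect_cut, p < alpha, and its
    BH FDR across the tested drugs is < fdr_cut.  Drugs where either group
    has fewer than *min_group* responses are skipped (logged).
    """
    g1, g2 = group_pair
    s1 = groups.index[groups == g1]
    s2 = groups.index[groups == g2]
    rows = []
    for drug in drug_matrix.columns:
        x1 = drug_matrix.loc[drug_matrix.index.intersection(s1), drug].dropna()
        x2 = drug_matrix.loc[drug_matrix.index.intersection(s2), drug].dropna()
        if len(x1) < min_group or len(x2) < min_group:
            log.info("drug %s skipped: group sizes %d/%d below %d", drug, len(x1), len(x2), min_group)
            continue
        effect = float(x1.mean() - x2.mean())
        if x1.nunique() == 1 and x2.nunique() == 1 and x1.iat[0] == x2.iat[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x1, x2, alternative="two-sided").pvalue)
        rows.append((drug, effect, p, len(x1), len(x2)))
    out = pd.DataFrame(rows, columns=["drug", "effect", "pvalue", f"n_{g1}", f"n_{g2}"])
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
        out["significant"] = (
            (out["effect"].abs() > effect_cut) & (out["pvalue"] < alpha) & (out["fdr"] < fdr_cut)
        )
    else:
        out["fdr"] = np.nan
        out["significant"] = pd.Series(dtype=bool)
    return out
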