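"""Joint mutation + expression screen.

Retains pairs with one recurrently mutated gene (frequency > 2% in at
least five cancer types) whose synthetic-lethal partner is recurrently
up-regulated (in more than 10 cancer types).  The mutated gene's own
expression is deliberately not filtered.  Both orientations of a pair are
tracked separately against the source file's original gene order.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._types import GenePair


@dataclass(frozen=True)
class CombinedPair:
    """One orientation of a pair passing the joint screen."""

    pair: GenePair
    mutated_gene: str
    partner_gene: str
    mutated_position: str  # "first" / "second" in original source order
    qualifying_mut_cancers: frozenset
    qualifying_up_cancers: frozenset

    def __post_init__(self):
        if self.mutated_gene == self.partner_gene:
            raise ValueError("mutated gene and partner must differ")
        if {self.mutated_gene, self.partner_gene} != set(self.pair.key):
            raise ValueError("genes must belong to the pair")
        if self.mutated_position not in ("first", "second"):
            raise ValueError("mutated_position must be 'first' or 'second'")


def _freq_lut(freqs: pd.DataFrame) -> dict[tuple[str, str], float]:
    return {
        (g, c): f
        for g, c, f in freqs[["gene", "cancer", "frequency"]].itertuples(index=False)
    }


def select_combined_pairs(
    catalog: list[GenePair],
    freqs: pd.DataFrame,
    matrix: pd.DataFrame,
    min_freq: float = 0.02,
    min_mut_cancers: int = 5,
    min_up_cancers: int = 11,
) -> list[CombinedPair]:
    """Screen the catalog for (mutated gene, up-regulated partner)
    orientations.

    An orientation qualifies iff the mutated gene's frequency exceeds
    *min_freq* in at least *min_mut_cancers* cancers and the partner's DE
    status is "up" (down-regulation does not count) in at least
    *min_up_cancers* cancers.  A pair qualifying in both orientations emits
    two records.  The mutated gene's own expression is never examined.
    """
    lut = _freq_lut(freqs)
    cancers = sorted(freqs["cancer"].unique())
    out = []
    for p in catalog:
        orig_first = p.orig_a if p.orig_a is not None else p.gene_a
        orig_second = p.orig_b if p.orig_b is not None else p.gene_b
        for mutated, partner in ((orig_first, orig_second), (orig_second, orig_first)):
            mut_cancers = frozenset(c for c in cancers if lut.get((mutated, c), 0.0) > min_freq)
            if len(mut_cancers) < min_mut_cancers:
                continue
            if partner in matrix.index:
                up_cancers = frozenset(matrix.columns[matrix.loc[partner] == "up"])
            else:
                up_cancers = frozenset()
            if len(up_cancers) < min_up_cancers:
                continue
            out.append(
                CombinedPair(
                    pair=p,
                    mutated_gene=mutated,
                    partner_gene=partner,
                    mutated_position="first" if mutated == orig_first else "second",
                    qualifying_mut_cancers=mut_cancers,
                    qualifying_up_cancers=up_cancers,
                )
            )
    return out


def positional_summary(pairs: list[CombinedPair], matrix: pd.DataFrame | None = None) -> dict:
    """Counts of mutated-first vs mutated-second orientations and, given
    the dysregulation matrix, the fraction of partner statuses that are
    "up" across the partners' full per-cancer profiles, per position."""
    counts = {"first": 0, "second": 0}
    up_frac = {}
    for cp in pairs:
        counts[cp.mutated_position] += 1
    if matrix is not None:
        for pos in ("first", "second"):
            partners = [cp.partner_gene for cp in pairs if cp.mutated_position == pos]
            n_up = n_total = 0
            for g in partners:
                if g in matrix.index:
                    row = matrix.loc[g]
                    n_up += int((row == "up").sum())
                    n_total += len(row)
            up_frac[pos] = n_up / n_total if n_total else float("nan")
    return {"counts": counts, "partner_up_fraction": up_frac}


def high_mutation_subset(
    pairs: list[CombinedPair], freqs: pd.DataFrame, high_freq: float = 0.03
) -> list[CombinedPair]:
    """Subset whose mutated gene exceeds *high_freq* in at least one
    cancer type."""
    lut = _freq_lut(freqs)
    cancers = sorted(freqs["cancer"].unique())
    return [
        cp
        for cp in pairs
        if any(lut.get((cp.mutated_gene, c), 0.0) > high_freq for c in cancers)
    ]


def combined_to_frame(pairs: list[CombinedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [cp.pair.gene_a for cp in pairs],
            "gene_b": [cp.pair.gene_b for cp in pairs],
            "mutated_gene": [cp.mutated_gene for cp in pairs],
            "partner_gene": [cp.partner_gene for cp in pairs],
            "mutated_position": [cp.mutated_position for cp in pairs],
            "qualifying_mut_cancers": [";".join(sorted(cp.qualifying_mut_cancers)) for cp in pairs],
            "qualifying_up_cancers": [";".join(sorted(cp.qualifying_up_cancers)) for cp in pairs],
        }
    )
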