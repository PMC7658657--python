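"""Core record types shared across the screening pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical names of the seven cancer-relevant gene characteristics.
CHARACTERISTIC_NAMES = (
    "hallmark",
    "cgc",
    "essential",
    "oncogene",
    "tsg",
    "actionable",
    "drug_target",
)

#: Variant classes carried on mutation calls, most common first.
VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice", "other")

#: Provenance labels for synthetic-lethal pairs.
PAIR_SOURCES = ("yeast_predicted", "human_predicted", "human_validated")


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Unordered-pair key: lexicographically sorted gene symbols."""
    if gene_a == gene_b:
        raise ValueError(f"self-pair not allowed: {gene_a}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


@dataclass(frozen=True)
class GenePair:
    """One candidate synthetic-lethal interaction.

    ``gene_a``/``gene_b`` are stored in canonical (lexicographic) order so
    that (x, y) and (y, x) are one record.  ``orig_a``/``orig_b`` preserve
    the order of the source file, which the positional analysis of the
    combined screen needs ("first gene" vs "second gene").
    """

    gene_a: str
    gene_b: str
    sources: frozenset = field(default_factory=frozenset)
    yeast_score: float | None = None
    orig_a: str | None = None
    orig_b: str | None = None

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair not allowed: {self.gene_a}")
        if self.gene_a > self.gene_b:
            raise ValueError("GenePair must be constructed in canonical order; use GenePair.make")
        if not self.sources:
            raise ValueError("GenePair requires at least one source label")
        unknown = set(self.sources) - set(PAIR_SOURCES)
        if unknown:
            raise ValueError(f"unknown pair source(s): {sorted(unknown)}")
        if "yeast_predicted" in self.sources and self.yeast_score is None:
            raise ValueError("yeast_predicted pair lacks a yeast score")

    @classmethod
    def make(
        cls,
        gene_a: str,
        gene_b: str,
        sources,
        yeast_score: float | None = None,
    ) -> "GenePair":
        a, b = canonical_pair(gene_a, gene_b)
        return cls(a, b, frozenset(sources), yeast_score, orig_a=gene_a, orig_b=gene_b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def merged_with(self, other: "GenePair") -> "GenePair":
        """Union sources; keep the most negative yeast score and the first
        seen original order."""
        if self.key != other.key:
            raise ValueError("cannot merge different pairs")
        scores = [s for s in (self.yeast_score, other.yeast_score) if s is not None]
        return GenePair(
            self.gene_a,
            self.gene_b,
            self.sources | other.sources,
            min(scores) if scores else None,
            orig_a=self.orig_a,
            orig_b=self.orig_b,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Binary characteristic flags for one gene."""

    gene: str
    characteristics: frozenset

    def __post_init__(self):
        unknown = set(self.characteristics) - set(CHARACTERISTIC_NAMES)
        if unknown:
            raise ValueError(f"unknown characteristic(s): {sorted(unknown)}")

    @property
    def n_characteristics(self) -> int:
        return len(self.characteristics)


@dataclass
class RandomizationResult:
    """Outcome of the empirical randomization test.

    ``empirical_p`` is the plain proportion of null draws with a statistic
    at least as large as the observed one (#{null >= observed} / B).
    """

    observed_stat: float
    null_stats: np.ndarray
    empirical_p: float
    B: int
    seed: int
    scheme: str
    statistic: str = "count"

    def __post_init__(self):
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        if len(self.null_stats) != self.B:
            raise ValueError("null_stats length must equal B")


@dataclass
class StageReport:
    """Auditable record counts for one pipeline stage."""

    stage: str
    records_in: int
    records_out: int
    thresholds: dict
    runtime_seconds: float = 0.0
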