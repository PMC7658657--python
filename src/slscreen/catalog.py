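"""Unified synthetic-lethal pair catalog.

Builds the candidate catalog from two provenances — yeast genetic
interactions transferred to human genes through an ortholog map, and
human predicted/validated pairs — then computes interaction-degree
statistics and annotates genes with cancer-relevant characteristics
(hallmark, CGC, essential, oncogene, TSG, actionable, drug target).
"""
from __future__ import annotations

import math
from collections import defaultdict
from pathlib import Path

import pandas as pd

from ._types import CHARACTERISTIC_NAMES, GeneAnnotation, GenePair, canonical_pair

#: Yeast genetic-interaction score cutoff: strongly negative scores mark
#: synthetic-lethal / sick interactions.
YEAST_SCORE_THRESHOLD = -0.35

#: Interaction-degree bins: singletons, 2-10, 11-50, hubs.
DEGREE_BINS = ("1", "2-10", "11-50", ">50")


# ---------------------------------------------------------------------------
# loading

def load_yeast_pairs(path, score_threshold: float = YEAST_SCORE_THRESHOLD) -> pd.DataFrame:
    """Load a yeast interaction TSV (gene_a, gene_b, score) and keep rows
    with score <= *score_threshold*.

    Self-pairs are dropped; unordered duplicates collapse keeping the most
    negative (strongest) score.  Malformed rows raise with the 1-based line
    number.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_a", "gene_b", "score"]:
            raise ValueError(f"{path}: expected columns gene_a, gene_b, score; got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}")
            try:
                score = float(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score: {parts[2]!r}") from None
            rows.append((parts[0], parts[1], score))

    best: dict[tuple[str, str], float] = {}
    for a, b, score in rows:
        if a == b or score > score_threshold:
            continue
        key = canonical_pair(a, b)
        if key not in best or score < best[key]:
            best[key] = score
    out = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(best.items())],
        columns=["gene_a", "gene_b", "score"],
    )
    return out


def load_human_pairs(path) -> list[GenePair]:
    """Load a human SL pair TSV (gene_a, gene_b, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    pairs: dict[tuple[str, str], GenePair] = {}
    for a, b, src in df[["gene_a", "gene_b", "source"]].itertuples(index=False):
        if a == b:
            continue
        p = GenePair.make(a, b, {src})
        if p.key in pairs:
            p = pairs[p.key].merged_with(p)
        pairs[p.key] = p
    return [pairs[k] for k in sorted(pairs)]


def load_ortholog_map(path) -> dict[str, set[str]]:
    """Load an ortholog TSV (yeast_gene, human_gene), one row per mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"yeast_gene", "human_gene"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns yeast_gene, human_gene")
    out: dict[str, set[str]] = defaultdict(set)
    for y, h in df[["yeast_gene", "human_gene"]].itertuples(index=False):
        out[y].add(h)
    return dict(out)


def load_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: set name, description, tab-separated members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs name, description, >=1 member")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# catalog construction

def map_orthologs(
    yeast_pairs: pd.DataFrame, ortholog_map: dict[str, set[str]]
) -> tuple[list[GenePair], int]:
    """Transfer yeast pairs onto human genes.

    Each yeast pair (a, b) expands to the Cartesian product of orthologs of
    a and of b; pairs with any unmapped member are dropped (counted, second
    return value), as are resulting self-pairs.  Every emitted pair carries
    source ``yeast_predicted`` and inherits the yeast score.
    """
    out: dict[tuple[str, str], GenePair] = {}
    n_dropped = 0
    for a, b, score in yeast_pairs[["gene_a", "gene_b", "score"]].itertuples(index=False):
        hs_a = ortholog_map.get(a)
        hs_b = ortholog_map.get(b)
        if not hs_a or not hs_b:
            n_dropped += 1
            continue
        for ha in sorted(hs_a):
            for hb in sorted(hs_b):
                if ha == hb:
                    continue
                p = GenePair.make(ha, hb, {"yeast_predicted"}, yeast_score=score)
                if p.key in out:
                    p = out[p.key].merged_with(p)
                out[p.key] = p
    return [out[k] for k in sorted(out)], n_dropped


def merge_catalog(
    yeast_derived: list[GenePair], human_db: list[GenePair]
) -> tuple[list[GenePair], dict]:
    """Unordered-pair union of the two provenances.

    Returns the unified catalog and a summary with pair/gene counts and the
    yeast-only / human-only / common gene partition.
    """
    merged: dict[tuple[str, str], GenePair] = {}
    for p in list(yeast_derived) + list(human_db):
        if p.key in merged:
            p = merged[p.key].merged_with(p)
        merged[p.key] = p
    catalog = [merged[k] for k in sorted(merged)]

    yeast_genes = {g for p in yeast_derived for g in p.key}
    human_genes = {g for p in human_db for g in p.key}
    summary = {
        "n_pairs": len(catalog),
        "n_genes": len(yeast_genes | human_genes),
        "n_genes_common": len(yeast_genes & human_genes),
        "n_genes_yeast_only": len(yeast_genes - human_genes),
        "n_genes_human_only": len(human_genes - yeast_genes),
    }
    return catalog, summary


# ---------------------------------------------------------------------------
# degree statistics

def _degree_bin(d: int) -> str:
    if d <= 1:
        return "1"
    if d <= 10:
        return "2-10"
    if d <= 50:
        return "11-50"
    return ">50"


def degree_distribution(catalog: list[GenePair]) -> tuple[pd.Series, pd.Series]:
    """Per-gene interaction degree and the binned degree distribution.

    degree(g) = number of distinct partners of g in the catalog.  Fractions
    are over all genes and sum to 1.
    """
    if not catalog:
        raise ValueError("degree_distribution requires a nonempty catalog")
    partners: dict[str, set[str]] = defaultdict(set)
    for p in catalog:
        partners[p.gene_a].add(p.gene_b)
        partners[p.gene_b].add(p.gene_a)
    degrees = pd.Series({g: len(v) for g, v in partners.items()}, name="degree").sort_index()
    binned = degrees.map(_degree_bin)
    fractions = binned.value_counts(normalize=True).reindex(DEGREE_BINS, fill_value=0.0)
    fractions.name = "fraction"
    return degrees, fractions


# ---------------------------------------------------------------------------
# gene characteristics

def annotate_genes(
    genes, characteristic_sets: dict[str, set[str]]
) -> tuple[list[GeneAnnotation], pd.Series]:
    """Flag each gene's membership in the seven characteristic sets.

    *characteristic_sets* must use exactly the canonical names.  Also
    returns per-characteristic coverage fractions over the gene list.
    """
    unknown = set(characteristic_sets) - set(CHARACTERISTIC_NAMES)
    if unknown:
        raise ValueError(f"unknown characteristic set name(s): {sorted(unknown)}")
    genes = list(genes)
    annotations = [
        GeneAnnotation(g, frozenset(name for name, s in characteristic_sets.items() if g in s))
        for g in genes
    ]
    n = max(len(genes), 1)
    coverage = pd.Series(
        {
            name: sum(1 for a in annotations if name in a.characteristics) / n
            for name in CHARACTERISTIC_NAMES
        },
        name="coverage",
    )
    return annotations, coverage


def select_core_genes(annotations: list[GeneAnnotation], min_characteristics: int = 4) -> list[str]:
    """Genes with at least *min_characteristics* characteristics, sorted by
    (-n_characteristics, symbol)."""
    kept = [a for a in annotations if a.n_characteristics >= min_characteristics]
    kept.sort(key=lambda a: (-a.n_characteristics, a.gene))
    return [a.gene for a in kept]


# ---------------------------------------------------------------------------
# persistence

def catalog_to_frame(catalog: list[GenePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in catalog],
            "gene_b": [p.gene_b for p in catalog],
            "sources": [";".join(sorted(p.sources)) for p in catalog],
            "yeast_score": [p.yeast_score if p.yeast_score is not None else math.nan for p in catalog],
            "original_order_a": [p.orig_a if p.orig_a is not None else p.gene_a for p in catalog],
            "original_order_b": [p.orig_b if p.orig_b is not None else p.gene_b for p in catalog],
        }
    )


def write_catalog(catalog: list[GenePair], path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        catalog_to_frame(catalog).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_catalog(path) -> list[GenePair]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        score = None if pd.isna(row.yeast_score) else float(row.yeast_score)
        p = GenePair(
            row.gene_a,
            row.gene_b,
            frozenset(str(row.sources).split(";")),
            score,
            orig_a=row.original_order_a,
            orig_b=row.original_order_b,
        )
        out.append(p)
    return out
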