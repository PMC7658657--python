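"""isomiR collapse, miRNA screening, and the miRNA-mRNA-SL network.

A miRNA locus is typically expressed as several sequence/length variants
(isomiRs); the most abundant one is taken as the locus representative and
its counts become the locus expression vector.  miRNAs down-regulated in
at least four cancer types are wired into a typed bipartite-plus-SL
network: mRNA-mRNA edges carry the synthetic-lethal interactions, typed
miRNA -> mRNA edges the regulatory targeting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._types import GeneAnnotation, GenePair
from . import de_engine

log = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGU")


@dataclass
class IsomiRRecord:
    """One isomiR of a miRNA locus with per-sample counts."""

    locus: str
    sequence: str
    counts: np.ndarray

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("T", "U")
        if not self.sequence or set(self.sequence) - RNA_ALPHABET:
            raise ValueError(f"invalid isomiR sequence {self.sequence!r}")
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("isomiR counts must be nonnegative")


def collapse_isomirs(
    records: list[IsomiRRecord],
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Pick each locus' dominant isomiR and return its expression vector.

    The representative is the isomiR with the largest total count across
    samples; ties break to the lexicographically smallest sequence.
    Returns (locus x sample count matrix, locus -> representative
    sequence, loci flagged because every isomiR total was zero).
    """
    if not records:
        raise ValueError("no isomiR records")
    by_locus: dict[str, list[IsomiRRecord]] = {}
    for r in records:
        by_locus.setdefault(r.locus, []).append(r)
    rows, reps, flagged = {}, {}, []
    for locus in sorted(by_locus):
        recs = by_locus[locus]
        totals = [int(r.counts.sum()) for r in recs]
        best = min(range(len(recs)), key=lambda i: (-totals[i], recs[i].sequence))
        if max(totals) == 0:
            flagged.append(locus)
            log.info("locus %s has all-zero isomiR totals; tie-break representative", locus)
        rows[locus] = recs[best].counts
        reps[locus] = recs[best].sequence
    return pd.DataFrame.from_dict(rows, orient="index"), reps, flagged


def read_isomir_tsv(path) -> list[IsomiRRecord]:
    """Read an isomiR TSV: locus, sequence, then one column per sample."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["locus", "sequence"]:
        raise ValueError(f"{path}: expected leading columns locus, sequence")
    return [
        IsomiRRecord(row[0], row[1], np.asarray(row[2:], dtype=int))
        for row in df.itertuples(index=False)
    ]


def mirna_de(
    collapsed: pd.DataFrame, labels: pd.Series, fc_cut: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Tumor-vs-normal DE on collapsed locus expression; delegates to the
    count-based DE engine with identical contracts."""
    return de_engine.de_test(collapsed, labels, fc_cut=fc_cut, alpha=alpha, pseudo_reference=True)


def select_down_mirnas(de_results: dict[str, pd.DataFrame], min_down_cancers: int = 4) -> list[str]:
    """miRNAs with status "down" in at least *min_down_cancers* cancers."""
    down_counts: dict[str, int] = {}
    for df in de_results.values():
        for gene, status in df[["gene", "status"]].itertuples(index=False):
            if status == "down":
                down_counts[gene] = down_counts.get(gene, 0) + 1
    return sorted(m for m, n in down_counts.items() if n >= min_down_cancers)


@dataclass
class RegulatoryNetwork:
    """Typed miRNA-mRNA-SL graph.

    Nodes carry ``kind`` ("mRNA"/"miRNA") plus expression-status and
    characteristic attributes; edges carry ``etype`` ("sl" between two
    mRNAs, "targets" from a miRNA to an mRNA).  Backed by a networkx
    DiGraph (sl edges stored once, on the canonical gene order).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    n_excluded_target_edges: int = 0

    def validate(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise AssertionError("self-loop in network")
            ku = self.graph.nodes[u]["kind"]
            kv = self.graph.nodes[v]["kind"]
            if data["etype"] == "sl":
                assert ku == kv == "mRNA", "sl edge must connect two mRNA nodes"
            elif data["etype"] == "targets":
                assert ku == "miRNA" and kv == "mRNA", "targets edge must be miRNA -> mRNA"
            else:
                raise AssertionError(f"unknown edge type {data['etype']!r}")

    def mirna_out_degree(self) -> pd.Series:
        mirnas = [n for n, d in self.graph.nodes(data=True) if d["kind"] == "miRNA"]
        return pd.Series({m: self.graph.out_degree(m) for m in mirnas}, dtype=int)

    def gene_in_degree(self) -> pd.Series:
        genes = [n for n, d in self.graph.nodes(data=True) if d["kind"] == "mRNA"]
        return pd.Series(
            {
                g: sum(1 for u, _, d in self.graph.in_edges(g, data=True) if d["etype"] == "targets")
                for g in genes
            },
            dtype=int,
        )


def build_network(
    genes,
    sl_edges: list[GenePair],
    target_map: dict[str, set[str]],
    selected_mirnas,
    annotations: list[GeneAnnotation] | None = None,
    expression_status: pd.DataFrame | None = None,
) -> RegulatoryNetwork:
    """Assemble the typed network over a screened gene list.

    Only targets edges from *selected_mirnas* into *genes* are admitted;
    edges pointing outside the screened list are dropped and counted.
    Node attributes carry characteristic flags (from *annotations*) and
    per-cancer expression status (from *expression_status*, genes x
    cancers).
    """
    genes = sorted(set(genes))
    gene_set = set(genes)
    ann_by_gene = {a.gene: a for a in (annotations or [])}
    g = nx.DiGraph()
    for gene in genes:
        attrs = {"kind": "mRNA"}
        if gene in ann_by_gene:
            a = ann_by_gene[gene]
            attrs["characteristics"] = ";".join(sorted(a.characteristics))
            attrs["essential"] = "essential" in a.characteristics
        if expression_status is not None and gene in expression_status.index:
            attrs["status"] = ";".join(
                f"{c}:{s}" for c, s in expression_status.loc[gene].items()
            )
        g.add_node(gene, **attrs)
    for p in sl_edges:
        if p.gene_a in gene_set and p.gene_b in gene_set:
            g.add_edge(p.gene_a, p.gene_b, etype="sl")
    n_excluded = 0
    for mirna in sorted(set(selected_mirnas)):
        targets = target_map.get(mirna, set())
        admitted = sorted(t for t in targets if t in gene_set)
        excluded = len(targets) - len(admitted)
        n_excluded += excluded
        if excluded:
            log.info("miRNA %s: %d target edge(s) outside the screened gene list", mirna, excluded)
        if admitted:
            g.add_node(mirna, kind="miRNA")
            for t in admitted:
                g.add_edge(mirna, t, etype="targets")
    net = RegulatoryNetwork(graph=g, n_excluded_target_edges=n_excluded)
    net.validate()
    return net


def network_summary(
    net: RegulatoryNetwork, pathway_sets: dict[str, set[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-pathway coverage of network mRNA nodes and characteristic
    tallies over annotated nodes."""
    mrnas = sorted(n for n, d in net.graph.nodes(data=True) if d["kind"] == "mRNA")
    rows = []
    for name in sorted(pathway_sets):
        members = sorted(set(mrnas) & pathway_sets[name])
        rows.append((name, len(members), len(mrnas), ";".join(members)))
    coverage = pd.DataFrame(rows, columns=["pathway", "n_in_network", "n_network_genes", "genes"])
    tallies: dict[str, int] = {}
    for n in mrnas:
        for c in net.graph.nodes[n].get("characteristics", "").split(";"):
            if c:
                tallies[c] = tallies.get(c, 0) + 1
    return coverage, pd.Series(tallies, dtype=int).sort_index()


def write_graphml(net: RegulatoryNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def write_sif(net: RegulatoryNetwork, path) -> None:
    """SIF export: `gene sl gene` and `mirna targets gene` lines."""
    with open(path, "w") as fh:
        for u, v, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{data['etype']}\t{v}\n")
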