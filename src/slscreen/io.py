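"""Readers/writers for the pipeline's plain-text interchange formats.

All outputs are TSV (or GMT/JSON/GraphML/SIF) with optional `#`-prefixed
header lines embedding the active config hash and seed, so silent
threshold drift shows up in an output diff.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def _write_with_header(df: pd.DataFrame, path, header_lines=None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_maf(calls: pd.DataFrame, path, header_lines=None) -> None:
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": calls["gene"],
            "Tumor_Sample_Barcode": calls["sample"],
            "Variant_Classification": calls["variant_class"],
            "cancer_type": calls["cancer"],
        }
    )
    _write_with_header(maf, path, header_lines)


def write_counts(counts: pd.DataFrame, labels: pd.Series, path_prefix, header_lines=None) -> None:
    """Count matrix TSV (genes x samples) plus a sample->condition sidecar."""
    _write_with_header(counts, f"{path_prefix}.counts.tsv", header_lines, index=True)
    sidecar = labels.rename("condition").rename_axis("sample").reset_index()
    _write_with_header(sidecar, f"{path_prefix}.conditions.tsv", header_lines)


def read_counts(path_prefix) -> tuple[pd.DataFrame, pd.Series]:
    counts = pd.read_csv(f"{path_prefix}.counts.tsv", sep="\t", comment="#", index_col=0)
    sidecar = pd.read_csv(f"{path_prefix}.conditions.tsv", sep="\t", comment="#")
    return counts, sidecar.set_index("sample")["condition"]


def write_clinical(clinical: pd.DataFrame, cancer: str, path, header_lines=None) -> None:
    out = clinical.rename_axis("sample").reset_index()
    out.insert(1, "cancer_type", cancer)
    out = out.rename(columns={"time": "time_days"})
    _write_with_header(out, path, header_lines)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.rename(columns={"time_days": "time"}).set_index("sample")[["time", "event"]]


def write_gmt(sets: dict, path, description: str = "synthetic") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def write_pairs(pairs, path, header_lines=None) -> None:
    """Pair-list TSV (gene_a, gene_b, source) in original source order."""
    rows = []
    for p in pairs:
        a = p.orig_a if p.orig_a is not None else p.gene_a
        b = p.orig_b if p.orig_b is not None else p.gene_b
        for src in sorted(p.sources):
            rows.append((a, b, src))
    _write_with_header(pd.DataFrame(rows, columns=["gene_a", "gene_b", "source"]), path, header_lines)


def write_target_map(target_map: dict, path, header_lines=None) -> None:
    rows = [(m, g) for m in sorted(target_map) for g in sorted(target_map[m])]
    _write_with_header(pd.DataFrame(rows, columns=["mirna", "gene"]), path, header_lines)


def read_target_map(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out: dict[str, set] = {}
    for m, g in df[["mirna", "gene"]].itertuples(index=False):
        out.setdefault(m, set()).add(g)
    return out


def write_drug_matrix(matrix: pd.DataFrame, path, header_lines=None) -> None:
    _write_with_header(matrix.rename_axis("sample"), path, header_lines, index=True)


def read_drug_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
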