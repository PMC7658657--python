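"""End-to-end orchestration of the screening cascade on synthetic data.

Runs, in dependency order: catalog construction and gene annotation, the
mutation-level screen with drug association, per-cancer differential
expression and the dysregulation screen, the combined mutation+expression
screen, survival grouping with the randomization test, and the
miRNA-mRNA network build.  Each stage contributes a StageReport with
record counts and the active thresholds; every output file header embeds
the config hash and seed, so a rerun with identical config and inputs is
byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    catalog as cat,
    combined_screen,
    de_engine,
    expression_screen,
    io,
    mirna_network,
    mutation_screen,
    survival_randomization as surv,
    synthetic_data as synth,
)
from ._types import StageReport


@dataclass
class Thresholds:
    """Every screening threshold of the cascade, with its default."""

    yeast_score_threshold: float = -0.35
    min_freq: float = 0.02
    min_mut_cancers: int = 5
    fc_cut: float = 1.5
    alpha: float = 0.05
    min_dysreg_cancers: int = 11
    min_up_cancers: int = 11
    effect_cut: float = 0.10
    fdr_cut: float = 0.10
    B: int = 1000
    min_down_cancers: int = 4
    high_freq: float = 0.03
    min_characteristics: int = 4
    z_cut: float = 1.96
    min_group: int = 5


@dataclass
class PipelineConfig:
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    generator: synth.GeneratorConfig = field(default_factory=synth.GeneratorConfig)
    n_samples_per_cancer: int = 100  # mutation / survival cohorts
    n_tumor: int = 60
    n_normal: int = 30
    dispersion: float = 0.1
    n_isomir_cancers: int = 4  # cancers profiled for small RNA
    survival_scheme: str = "two_group"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            _check_fields(Thresholds, kwargs["thresholds"], "thresholds")
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "generator" in kwargs:
            _check_fields(synth.GeneratorConfig, kwargs["generator"], "generator")
            kwargs["generator"] = synth.GeneratorConfig(**kwargs["generator"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _check_fields(cls, raw, path):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s) under {path}: {sorted(unknown)}")


@dataclass
class PipelineResult:
    truth: synth.PlantedTruth
    catalog: list
    reports: list
    mutated_pairs: pd.DataFrame
    dysregulation: pd.DataFrame
    dysregulated_genes: list
    dysregulated_pairs: list
    combined_pairs: list
    high_mut_pairs: list
    survival_table: pd.DataFrame | None
    randomization: object | None
    drug_table: pd.DataFrame | None
    network: mirna_network.RegulatoryNetwork | None
    down_mirnas: list

    def stage_counts(self) -> dict:
        return {r.stage: {"in": r.records_in, "out": r.records_out} for r in self.reports}


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run the full cascade on a synthetic study defined by *config*.

    If *out_dir* is given, each stage writes its TSV/JSON output there
    with config-hash-stamped headers.
    """
    th = config.thresholds
    header = [f"config_hash={config.hash()}", f"seed={config.seed}"]
    reports: list[StageReport] = []
    out = Path(out_dir) if out_dir is not None else None

    def report(stage, n_in, n_out, thresholds, t0):
        reports.append(StageReport(stage, n_in, n_out, thresholds, time.perf_counter() - t0))

    # --- stage: synthetic inputs -------------------------------------------
    t0 = time.perf_counter()
    truth = synth.generate_truth(config.generator, config.seed)
    calls, cohorts = synth.generate_mutations(truth, config.n_samples_per_cancer, seed=1)
    counts_by_cancer = synth.generate_counts(
        truth, config.n_tumor, config.n_normal, dispersion=config.dispersion, seed=2
    )
    report("simulate", 0, len(truth.sl_pairs), {"seed": config.seed}, t0)

    # --- stage: catalog ----------------------------------------------------
    t0 = time.perf_counter()
    yeast_derived = [p for p in truth.sl_pairs if "yeast_predicted" in p.sources]
    human_db = [p for p in truth.sl_pairs if "yeast_predicted" not in p.sources]
    catalog, cat_summary = cat.merge_catalog(yeast_derived, human_db)
    degrees, degree_bins = cat.degree_distribution(catalog)
    genes_in_catalog = sorted(degrees.index)
    annotations, coverage = cat.annotate_genes(genes_in_catalog, truth.characteristic_sets)
    core_genes = cat.select_core_genes(annotations, th.min_characteristics)
    report(
        "catalog",
        len(truth.sl_pairs),
        len(catalog),
        {"min_characteristics": th.min_characteristics},
        t0,
    )
    if out:
        cat.write_catalog(catalog, out / "catalog.tsv", header)
        io._write_with_header(
            degree_bins.rename_axis("bin").reset_index(), out / "degree_bins.tsv", header
        )

    # --- stage: mutation screen -------------------------------------------
    t0 = time.perf_counter()
    freqs = mutation_screen.mutation_frequency(calls, cohorts)
    mutated_pairs = mutation_screen.select_mutated_pairs(
        catalog, freqs, th.min_freq, th.min_mut_cancers
    )
    report(
        "mutation_screen",
        len(catalog),
        len(mutated_pairs),
        {"min_freq": th.min_freq, "min_mut_cancers": th.min_mut_cancers},
        t0,
    )
    if out:
        io._write_with_header(mutated_pairs, out / "mutated_pairs.tsv", header)

    # --- stage: expression screen -----------------------------------------
    t0 = time.perf_counter()
    de_results = {
        cancer: de_engine.de_test(counts, labels, th.fc_cut, th.alpha)
        for cancer, (counts, labels) in counts_by_cancer.items()
    }
    matrix = expression_screen.build_dysregulation_matrix(de_results)
    dys_genes = expression_screen.select_dysregulated_genes(matrix, th.min_dysreg_cancers)
    dys_pairs = expression_screen.select_dysregulated_pairs(catalog, dys_genes)
    report(
        "expression_screen",
        len(catalog),
        len(dys_pairs),
        {"fc_cut": th.fc_cut, "alpha": th.alpha, "min_dysreg_cancers": th.min_dysreg_cancers},
        t0,
    )
    if out:
        io._write_with_header(
            matrix.rename_axis("gene").reset_index(), out / "dysregulation_matrix.tsv", header
        )

    # --- stage: combined screen -------------------------------------------
    t0 = time.perf_counter()
    combined = combined_screen.select_combined_pairs(
        catalog, freqs, matrix, th.min_freq, th.min_mut_cancers, th.min_up_cancers
    )
    high_mut = combined_screen.high_mutation_subset(combined, freqs, th.high_freq)
    report(
        "combined_screen",
        len(catalog),
        len(combined),
        {"min_freq": th.min_freq, "min_mut_cancers": th.min_mut_cancers,
         "min_up_cancers": th.min_up_cancers, "high_freq": th.high_freq},
        t0,
    )
    if out:
        io._write_with_header(
            combined_screen.combined_to_frame(combined), out / "combined_pairs.tsv", header
        )

    # --- stage: survival + randomization ----------------------------------
    t0 = time.perf_counter()
    survival_table = randomization = None
    surv_cancer = truth.cancers[0]
    cohort = sorted({f"{surv_cancer}-S{j:04d}" for j in range(config.n_samples_per_cancer)})
    observed = [p for p in catalog if (p.key, surv_cancer) in truth.prognostic_pairs]
    if observed:
        group_cache: dict = {}

        def builder(key):
            if key not in group_cache:
                pair = _KeyPair(key)
                group_cache[key] = mutation_screen.assign_mutation_groups(
                    pair, calls, surv_cancer, cohort
                )
            return group_cache[key]

        mult = pd.Series(1.0, index=pd.Index(cohort))
        for p in observed:
            hr_map = truth.prognostic_pairs[(p.key, surv_cancer)]
            mult *= builder(p.key).map(hr_map).astype(float)
        clinical = synth.generate_clinical(
            pd.Series("WW", index=pd.Index(cohort)),
            hazard_multiplier=mult,
            seed=config.seed,
        )
        groupings = {p.key: builder(p.key) for p in observed}
        survival_table, n_sig = surv.pair_prognostic_scan(
            observed, groupings, clinical, config.survival_scheme, th.alpha, th.min_group
        )
        randomization = surv.randomization_test(
            observed,
            truth.gene_universe,
            {p.key for p in catalog},
            clinical,
            builder,
            B=th.B,
            seed=config.seed,
            scheme=config.survival_scheme,
            alpha=th.alpha,
            min_group=th.min_group,
        )
        if out:
            io._write_with_header(survival_table, out / "survival_pairs.tsv", header)
            io.write_json(
                {
                    "observed": randomization.observed_stat,
                    "B": randomization.B,
                    "seed": randomization.seed,
                    "scheme": randomization.scheme,
                    "empirical_p": randomization.empirical_p,
                    "null_mean": float(np.mean(randomization.null_stats)),
                    "null_max": float(np.max(randomization.null_stats)),
                },
                out / "randomization.json",
            )
    report(
        "survival",
        len(observed),
        int(survival_table["tested"].sum()) if survival_table is not None else 0,
        {"scheme": config.survival_scheme, "alpha": th.alpha,
         "min_group": th.min_group, "B": th.B},
        t0,
    )

    # --- stage: drug association ------------------------------------------
    t0 = time.perf_counter()
    drug_table = None
    if truth.drug_effects:
        focal_key = next(iter(sorted(truth.drug_effects)))[0]
        groups = mutation_screen.assign_mutation_groups(
            _KeyPair(focal_key), calls, surv_cancer, cohort
        )
        drug_matrix = synth.generate_drug_response(truth, groups, focal_key, seed=config.seed)
        drug_table = mutation_screen.drug_association(
            groups, drug_matrix, ("MM", "WW"), th.effect_cut, th.alpha, th.fdr_cut
        )
        if out:
            io._write_with_header(drug_table, out / "drug_association.tsv", header)
    report(
        "drug_association",
        len(drug_table) if drug_table is not None else 0,
        int(drug_table["significant"].sum()) if drug_table is not None and len(drug_table) else 0,
        {"effect_cut": th.effect_cut, "alpha": th.alpha, "fdr_cut": th.fdr_cut},
        t0,
    )

    # --- stage: miRNA network ---------------------------------------------
    t0 = time.perf_counter()
    mirna_de_results = {}
    iso_cancers = truth.cancers[: config.n_isomir_cancers]
    for cancer in iso_cancers:
        n_t, n_n = config.n_tumor, config.n_normal
        names = [f"{cancer}-T{j:03d}" for j in range(n_t)] + [
            f"{cancer}-N{j:03d}" for j in range(n_n)
        ]
        labels = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=names)
        iso_table = synth.generate_isomirs(
            truth, n_t + n_n, seed=3, cancer=cancer, labels=labels, sample_names=names
        )
        records = [
            mirna_network.IsomiRRecord(r[0], r[1], np.asarray(r[2:], dtype=int))
            for r in iso_table.itertuples(index=False)
        ]
        collapsed, _reps, _flagged = mirna_network.collapse_isomirs(records)
        collapsed.columns = names
        mirna_de_results[cancer] = mirna_network.mirna_de(collapsed, labels, th.fc_cut, th.alpha)
    down_mirnas = mirna_network.select_down_mirnas(mirna_de_results, th.min_down_cancers)
    net_genes = sorted(
        {cp.mutated_gene for cp in high_mut} | {cp.partner_gene for cp in high_mut}
    )
    network = mirna_network.build_network(
        net_genes,
        [cp.pair for cp in high_mut],
        truth.target_map,
        down_mirnas,
        annotations=annotations,
        expression_status=matrix,
    )
    report(
        "mirna_network",
        len(truth.isomir_profile),
        network.graph.number_of_edges(),
        {"min_down_cancers": th.min_down_cancers},
        t0,
    )
    if out:
        mirna_network.write_graphml(network, out / "network.graphml")
        mirna_network.write_sif(network, out / "network.sif")
        io.write_json(
            {r.stage: {"records_in": r.records_in, "records_out": r.records_out,
                       "thresholds": r.thresholds} for r in reports},
            out / "stage_report.json",
        )

    return PipelineResult(
        truth=truth,
        catalog=catalog,
        reports=reports,
        mutated_pairs=mutated_pairs,
        dysregulation=matrix,
        dysregulated_genes=dys_genes,
        dysregulated_pairs=dys_pairs,
        combined_pairs=combined,
        high_mut_pairs=high_mut,
        survival_table=survival_table,
        randomization=randomization,
        drug_table=drug_table,
        network=network,
        down_mirnas=down_mirnas,
    )


class _KeyPair:
    """Light pair-key adapter exposing the GenePair surface the group
    assigners need."""

    def __init__(self, key):
        self.gene_a, self.gene_b = key
        self.key = tuple(key)


# ---------------------------------------------------------------------------
# fixture workflow

FIXTURE_CONFIG = dict(
    generator=dict(
        n_genes=150,
        n_cancers=12,
        n_pairs=30,
        n_mut_signal_pairs=2,
        n_expr_signal_pairs=2,
        n_combined_pairs=3,
        n_prognostic_pairs=2,
        n_de_cancers=11,
        n_loci=24,
        n_down_mirnas=4,
        n_drug_effect_pairs=2,
    ),
    n_samples_per_cancer=80,
    n_tumor=30,
    n_normal=15,
    thresholds=dict(B=200),
)


def make_fixture(seed: int, out_dir) -> dict:
    """Generate the small packaged synthetic study and its manifest.

    Writes every pipeline input format (MAF, counts + sidecars, clinical,
    isomiR table, drug matrix, GMT, pair list, target map), runs the full
    cascade, and records the expected stage counts and recovered pairs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw = dict(FIXTURE_CONFIG)
    raw["seed"] = seed
    config = PipelineConfig.from_dict(raw)
    header = [f"config_hash={config.hash()}", f"seed={seed}"]

    truth = synth.generate_truth(config.generator, seed)
    calls, cohorts = synth.generate_mutations(truth, config.n_samples_per_cancer, seed=1)
    io.write_maf(calls, out / "mutations.maf.tsv", header)
    counts_by_cancer = synth.generate_counts(
        truth, config.n_tumor, config.n_normal, seed=2,
        cancers=truth.cancers[:2],  # two example matrices; the run regenerates the rest
    )
    for cancer, (counts, labels) in counts_by_cancer.items():
        io.write_counts(counts, labels, out / f"expression.{cancer}", header)
    io.write_gmt(truth.characteristic_sets, out / "characteristics.gmt")
    io.write_pairs(truth.sl_pairs, out / "pairs.tsv", header)
    io.write_target_map(truth.target_map, out / "targets.tsv", header)

    result = run_pipeline(config, out_dir=out / "results")
    manifest = {
        "seed": seed,
        "config_hash": config.hash(),
        "stage_counts": result.stage_counts(),
        "combined_pairs": sorted(
            f"{cp.mutated_gene}:{cp.partner_gene}" for cp in result.combined_pairs
        ),
        "planted_combined": sorted(
            f"{m}:{p}" for (_pair, m, p) in result.truth.combined_signal
        ),
        "down_mirnas": result.down_mirnas,
        "empirical_p": result.randomization.empirical_p if result.randomization else None,
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
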