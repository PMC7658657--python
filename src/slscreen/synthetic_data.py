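"""Synthetic pan-cancer data with planted, recorded ground truth.

Every pipeline input — the SL pair catalog sources, MAF-style mutation
calls, tumor/normal RNA count matrices, clinical survival tables, isomiR
count tables, miRNA target maps, characteristic gene sets, and drug
response matrices — can be generated here with known planted signal:
recurrently mutated genes, differentially expressed genes, group-dependent
survival hazards, dominant isomiRs, and drug-response shifts.  All
generators are deterministic for a fixed (config, seed); one global seed
fans out to fixed per-generator child streams, so adding a generator does
not perturb the others.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._types import CHARACTERISTIC_NAMES, VARIANT_CLASSES, GenePair

#: Fixed stream codes of the seed-splitting rule (never renumber).
_STREAMS = {
    "truth": 1,
    "mutations": 2,
    "counts": 3,
    "clinical": 4,
    "isomirs": 5,
    "drugs": 6,
}

DEFAULT_VARIANT_PROBS = {
    "missense": 0.6,
    "nonsense": 0.1,
    "frameshift": 0.1,
    "splice": 0.1,
    "other": 0.1,
}


def child_rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    """Per-generator child stream of the global seed."""
    return np.random.default_rng([seed, _STREAMS[stream], extra])


@dataclass
class GeneratorConfig:
    """Settings of the synthetic study.

    Defaults describe a pan-cancer screen at desk scale: 20 cancer types,
    500 genes, a 50-pair null catalog, and (when requested) planted signal
    genes mutated at 10% in 8 cancer types against a 0.5% background, or
    differentially expressed at |log2FC| = 2.5 in 12 cancer types.
    """

    n_genes: int = 500
    n_cancers: int = 20
    n_pairs: int = 50  # null (filler) catalog pairs, on top of planted ones
    n_mut_signal_pairs: int = 0
    n_expr_signal_pairs: int = 0
    n_combined_pairs: int = 0
    n_prognostic_pairs: int = 0
    prognostic_mut_rate: float = 0.40  # in the survival cancer, so MM/MW/WW are populated
    survival_background_mut_rate: float = 0.30  # survival-cancer rate for all genes
    background_mut_rate: float = 0.005
    signal_mut_rate: float = 0.10
    n_mut_cancers: int = 8
    signal_lfc: float = 2.5
    n_de_cancers: int = 12
    prognostic_hr: float = 3.0
    n_loci: int = 20
    isomirs_per_locus: int = 3
    dominant_prop: float = 0.7
    n_down_mirnas: int = 5
    n_mirna_down_cancers: int = 4
    mirna_lfc: float = -2.0
    mirna_targets_per_locus: int = 4
    n_drugs: int = 8
    n_drug_effect_pairs: int = 0
    drug_shift: float = 0.3
    variant_class_probs: dict = field(default_factory=lambda: dict(DEFAULT_VARIANT_PROBS))

    def validate(self) -> None:
        if self.n_genes < 20:
            raise ValueError("need n_genes >= 20")
        if self.n_cancers < 1 or self.n_pairs < 1:
            raise ValueError("need n_cancers >= 1 and n_pairs >= 1")
        if (self.n_mut_signal_pairs or self.n_combined_pairs) and self.n_cancers < 5:
            raise ValueError("mutation-signal pairs need n_cancers >= 5 (screen unreachable)")
        if (self.n_expr_signal_pairs or self.n_combined_pairs) and self.n_cancers < 11:
            raise ValueError("expression-signal pairs need n_cancers >= 11 (screen unreachable)")
        if not 0 <= self.background_mut_rate <= 1 or not 0 <= self.signal_mut_rate <= 1:
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.n_mut_cancers < 5 and (self.n_mut_signal_pairs or self.n_combined_pairs):
            raise ValueError("signal genes must be mutated in >= 5 cancers to satisfy the screen")
        if self.n_de_cancers < 11 and (self.n_expr_signal_pairs or self.n_combined_pairs):
            raise ValueError("signal genes must be deregulated in >= 11 cancers to satisfy the screen")
        if abs(sum(self.variant_class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("variant class probabilities must sum to 1")
        if set(self.variant_class_probs) != set(VARIANT_CLASSES):
            raise ValueError(f"variant classes must be exactly {VARIANT_CLASSES}")


@dataclass
class PlantedTruth:
    """Recorded ground truth of one synthetic study."""

    gene_universe: list
    cancers: list
    sl_pairs: list  # GenePair, planted + filler
    characteristic_sets: dict
    mutation_freq: pd.DataFrame  # genes x cancers Bernoulli rates
    de_effect: pd.DataFrame  # genes x cancers planted log2 fold changes
    prognostic_pairs: dict  # (pair key, cancer) -> {group label: hazard ratio}
    isomir_profile: dict  # locus -> (sequences, proportions, dominant index)
    mirna_de_effect: pd.DataFrame  # loci x cancers planted log2 fold changes
    target_map: dict  # miRNA -> gene set
    drug_effects: dict  # (pair key, drug) -> planted mean response shift
    seed: int
    # planted-signal bookkeeping
    mut_signal_pairs: list = field(default_factory=list)
    expr_signal_pairs: list = field(default_factory=list)
    combined_signal: list = field(default_factory=list)  # (pair, mutated_gene, partner)

    def validate(self) -> None:
        universe = set(self.gene_universe)
        for p in self.sl_pairs:
            assert p.gene_a in universe and p.gene_b in universe
        for s in self.characteristic_sets.values():
            assert s <= universe
        for targets in self.target_map.values():
            assert targets <= universe
        rates = self.mutation_freq.to_numpy()
        assert np.all((rates >= 0) & (rates <= 1))
        for locus, (seqs, props, dom) in self.isomir_profile.items():
            props = np.asarray(props)
            assert abs(props.sum() - 1.0) < 1e-9, locus
            assert np.all(props[dom] > np.delete(props, dom)), locus


def _random_pairs(rng, genes, n, taken: set) -> list[tuple[str, str]]:
    out = []
    genes = list(genes)
    while len(out) < n:
        i, j = rng.integers(0, len(genes), size=2)
        if i == j:
            continue
        a, b = sorted((genes[i], genes[j]))
        if (a, b) in taken:
            continue
        taken.add((a, b))
        out.append((a, b))
    return out


def _random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def generate_truth(config: GeneratorConfig, seed: int) -> PlantedTruth:
    """Plant the ground truth for one synthetic study.

    Planted signal genes are disjoint between categories and disjoint from
    the genes used by filler (null) pairs, so every screen's expected
    output set is well defined.  Signal pairs satisfy the screen
    thresholds by construction.
    """
    config.validate()
    rng = child_rng(seed, "truth")
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    cancers = [f"C{i:02d}" for i in range(config.n_cancers)]

    n_signal_genes = 2 * (
        config.n_mut_signal_pairs + config.n_expr_signal_pairs
        + config.n_combined_pairs + config.n_prognostic_pairs
    )
    if n_signal_genes > config.n_genes // 2:
        raise ValueError("too many planted pairs for the gene universe")
    pool = [str(g) for g in rng.permutation(genes)]
    signal_genes = [pool.pop() for _ in range(n_signal_genes)]
    background = pool

    mutation_freq = pd.DataFrame(
        config.background_mut_rate, index=genes, columns=cancers, dtype=float
    )
    if config.n_prognostic_pairs:
        # the survival cancer carries a realistic mutation load so that
        # random (non-SL) pairs also form testable MM/MW/WW groups there
        mutation_freq[cancers[0]] = config.survival_background_mut_rate
    de_effect = pd.DataFrame(0.0, index=genes, columns=cancers)

    taken: set[tuple[str, str]] = set()
    sl_pairs: list[GenePair] = []
    mut_signal, expr_signal, combined = [], [], []
    prognostic: dict = {}

    def _plant_mut(gene, cancer_subset):
        mutation_freq.loc[gene, cancer_subset] = config.signal_mut_rate

    def _plant_de(gene, cancer_subset, lfc):
        de_effect.loc[gene, cancer_subset] = lfc

    it = iter(signal_genes)
    for _ in range(config.n_mut_signal_pairs):
        a, b = next(it), next(it)
        subset = list(rng.choice(cancers, size=config.n_mut_cancers, replace=False))
        _plant_mut(a, subset)
        _plant_mut(b, subset)
        p = GenePair.make(a, b, {"human_validated"})
        taken.add(p.key)
        sl_pairs.append(p)
        mut_signal.append(p)
    for _ in range(config.n_expr_signal_pairs):
        a, b = next(it), next(it)
        subset = list(rng.choice(cancers, size=config.n_de_cancers, replace=False))
        _plant_de(a, subset, config.signal_lfc)
        _plant_de(b, subset, config.signal_lfc)
        p = GenePair.make(a, b, {"human_validated"})
        taken.add(p.key)
        sl_pairs.append(p)
        expr_signal.append(p)
    for _ in range(config.n_combined_pairs):
        mutated, partner = next(it), next(it)
        _plant_mut(mutated, list(rng.choice(cancers, size=config.n_mut_cancers, replace=False)))
        _plant_de(partner, list(rng.choice(cancers, size=config.n_de_cancers, replace=False)),
                  abs(config.signal_lfc))
        p = GenePair.make(mutated, partner, {"human_predicted"})
        taken.add(p.key)
        sl_pairs.append(p)
        combined.append((p, mutated, partner))
    hr = config.prognostic_hr
    hr_map = {"MM": hr, "MW": hr ** 0.5, "WW": 1.0, "AA": hr, "AN": hr ** 0.5, "NN": 1.0}
    prognostic_pair_objs = []
    for _ in range(config.n_prognostic_pairs):
        a, b = next(it), next(it)
        # mutated often in the survival cancer so all three groups exist
        mutation_freq.loc[a, cancers[0]] = config.prognostic_mut_rate
        mutation_freq.loc[b, cancers[0]] = config.prognostic_mut_rate
        p = GenePair.make(a, b, {"human_validated"})
        taken.add(p.key)
        sl_pairs.append(p)
        prognostic_pair_objs.append(p)
        prognostic[(p.key, cancers[0])] = dict(hr_map)

    for a, b in _random_pairs(rng, background, config.n_pairs, taken):
        source = ["yeast_predicted", "human_predicted", "human_validated"][int(rng.integers(3))]
        score = float(-0.35 - 0.45 * rng.random()) if source == "yeast_predicted" else None
        sl_pairs.append(GenePair.make(a, b, {source}, yeast_score=score))

    characteristic_sets = {
        name: set(map(str, rng.choice(genes, size=max(1, int(0.15 * config.n_genes)), replace=False)))
        for name in CHARACTERISTIC_NAMES
    }
    # guarantee a handful of core genes carrying >= 4 characteristics
    for g in background[:10]:
        for name in list(characteristic_sets)[:5]:
            characteristic_sets[name].add(g)

    isomir_profile = {}
    loci = [f"mir-{i:04d}" for i in range(config.n_loci)]
    for locus in loci:
        k = config.isomirs_per_locus
        seqs = []
        while len(seqs) < k:
            s = _random_rna(rng, int(rng.integers(20, 25)))
            if s not in seqs:
                seqs.append(s)
        rest = rng.dirichlet(np.full(max(k - 1, 1), 5.0)) * (1.0 - config.dominant_prop)
        dom = int(rng.integers(k))
        props = np.insert(rest, dom, config.dominant_prop) if k > 1 else np.array([1.0])
        props = props / props.sum()
        isomir_profile[locus] = (seqs, props, dom)

    mirna_de_effect = pd.DataFrame(0.0, index=loci, columns=cancers)
    down_loci = loci[: config.n_down_mirnas]
    # planted in the leading cancers: small-RNA profiling covers a cancer
    # subset and must include every planted down-regulation
    for locus in down_loci:
        mirna_de_effect.loc[locus, cancers[: config.n_mirna_down_cancers]] = config.mirna_lfc

    partner_genes = [c[2] for c in combined]
    target_map = {}
    for locus in loci:
        targets = set(map(str, rng.choice(genes, size=config.mirna_targets_per_locus, replace=False)))
        if locus in down_loci and partner_genes:
            targets.add(partner_genes[int(rng.integers(len(partner_genes)))])
        target_map[locus] = targets

    drugs = [f"D{i:02d}" for i in range(config.n_drugs)]
    drug_effects = {}
    # plant response shifts on pairs whose MM group is populated: the
    # prognostic pairs first, then combined pairs, then the catalog head
    drug_candidates = prognostic_pair_objs + [c[0] for c in combined] + sl_pairs
    for p in drug_candidates[: config.n_drug_effect_pairs]:
        drug = drugs[int(rng.integers(len(drugs)))]
        drug_effects[(p.key, drug)] = config.drug_shift

    truth = PlantedTruth(
        gene_universe=genes,
        cancers=cancers,
        sl_pairs=sl_pairs,
        characteristic_sets=characteristic_sets,
        mutation_freq=mutation_freq,
        de_effect=de_effect,
        prognostic_pairs=prognostic,
        isomir_profile=isomir_profile,
        mirna_de_effect=mirna_de_effect,
        target_map=target_map,
        drug_effects=drug_effects,
        seed=seed,
        mut_signal_pairs=mut_signal,
        expr_signal_pairs=expr_signal,
        combined_signal=combined,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# downstream generators

def generate_mutations(
    truth: PlantedTruth,
    n_samples_per_cancer: int,
    seed: int,
    variant_class_probs: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """MAF-style mutation calls; gene g is mutated in a sample of cancer c
    with probability mutation_freq[g, c].

    Returns (call table with columns sample, gene, cancer, variant_class;
    cohort sizes per cancer).
    """
    if n_samples_per_cancer < 1:
        raise ValueError("need n_samples_per_cancer >= 1")
    probs = variant_class_probs or DEFAULT_VARIANT_PROBS
    pvec = np.array([probs[v] for v in VARIANT_CLASSES])
    rng = child_rng(truth.seed, "mutations", seed)
    genes = np.asarray(truth.gene_universe)
    frames = []
    for cancer in truth.cancers:
        rates = truth.mutation_freq[cancer].to_numpy()
        hits = rng.random((genes.size, n_samples_per_cancer)) < rates[:, None]
        gi, si = np.nonzero(hits)
        if gi.size == 0:
            continue
        classes = rng.choice(VARIANT_CLASSES, size=gi.size, p=pvec)
        frames.append(
            pd.DataFrame(
                {
                    "sample": [f"{cancer}-S{j:04d}" for j in si],
                    "gene": genes[gi],
                    "cancer": cancer,
                    "variant_class": classes,
                }
            )
        )
    calls = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["sample", "gene", "cancer", "variant_class"])
    )
    cohorts = {c: n_samples_per_cancer for c in truth.cancers}
    return calls, cohorts


def _nb_draw(rng, mean, dispersion):
    """Negative binomial with var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_counts(
    truth: PlantedTruth,
    n_tumor: int,
    n_normal: int,
    dispersion: float = 0.1,
    base_mean_range: tuple[float, float] = (50.0, 2000.0),
    seed: int = 0,
    cancers: list | None = None,
) -> dict[str, tuple[pd.DataFrame, pd.Series]]:
    """Per-cancer negative-binomial gene x sample count matrices.

    Normal-sample means are drawn log-uniformly per gene from
    *base_mean_range*; tumor means are scaled by 2**de_effect[g, c].
    Returns {cancer: (counts, condition labels)}.
    """
    if n_tumor < 2 or n_normal < 2:
        raise ValueError("need >= 2 tumor and >= 2 normal samples")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = child_rng(truth.seed, "counts", seed)
    lo, hi = base_mean_range
    out = {}
    genes = truth.gene_universe
    for cancer in cancers if cancers is not None else truth.cancers:
        mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
        lfc = truth.de_effect[cancer].to_numpy()
        mu_tumor = mu * np.exp2(lfc)
        counts_t = _nb_draw(rng, np.repeat(mu_tumor[:, None], n_tumor, axis=1), dispersion)
        counts_n = _nb_draw(rng, np.repeat(mu[:, None], n_normal, axis=1), dispersion)
        cols_t = [f"{cancer}-T{j:03d}" for j in range(n_tumor)]
        cols_n = [f"{cancer}-N{j:03d}" for j in range(n_normal)]
        counts = pd.DataFrame(
            np.hstack([counts_t, counts_n]), index=genes, columns=cols_t + cols_n
        )
        labels = pd.Series(
            ["tumor"] * n_tumor + ["normal"] * n_normal, index=counts.columns, name="condition"
        )
        out[cancer] = (counts, labels)
    return out


def generate_clinical(
    group_labels: pd.Series,
    hazard_ratios: dict | None = None,
    baseline_hazard: float = 1.0 / 1000,
    censor_hazard: float = 0.43 / 1000,
    seed: int = 0,
    hazard_multiplier: pd.Series | None = None,
) -> pd.DataFrame:
    """Exponential survival with group-dependent hazards.

    Event time ~ Exp(baseline_hazard * HR(group)); censoring time is an
    independent exponential.  ``hazard_multiplier`` (per-sample) overrides
    the group lookup, supporting hazards that depend on several planted
    pairs at once.  Returns a table indexed by sample with columns time
    (days, > 0) and event (1 = death observed).
    """
    if baseline_hazard <= 0 or censor_hazard < 0:
        raise ValueError("hazards must be positive (censor hazard may be 0)")
    rng = np.random.default_rng([seed, _STREAMS["clinical"]])
    if hazard_multiplier is None:
        hr = {**{g: 1.0 for g in group_labels.unique()}, **(hazard_ratios or {})}
        mult = group_labels.map(hr).astype(float)
    else:
        mult = hazard_multiplier.reindex(group_labels.index).astype(float)
    hazard = baseline_hazard * mult.to_numpy()
    t_event = rng.exponential(1.0 / hazard)
    if censor_hazard > 0:
        t_censor = rng.exponential(1.0 / censor_hazard, size=hazard.size)
    else:
        t_censor = np.full(hazard.size, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame(
        {"time": np.maximum(time, 1e-9), "event": event}, index=group_labels.index
    )


def generate_isomirs(
    truth: PlantedTruth,
    n_samples: int,
    locus_total_mean: float = 2000.0,
    seed: int = 0,
    dispersion: float = 0.1,
    cancer: str | None = None,
    labels: pd.Series | None = None,
    sample_names: list | None = None,
) -> pd.DataFrame:
    """isomiR count table (columns: locus, sequence, then samples).

    Per sample, the locus total is negative-binomial around
    *locus_total_mean* and isomiR counts are multinomial with the planted
    proportion vector.  If *cancer* and per-sample tumor/normal *labels*
    are given, tumor locus totals are scaled by
    2**mirna_de_effect[locus, cancer].
    """
    if locus_total_mean <= 0:
        raise ValueError("locus_total_mean must be positive")
    rng = child_rng(truth.seed, "isomirs", seed)
    if sample_names is None:
        sample_names = [f"M-S{j:04d}" for j in range(n_samples)]
    rows = []
    for locus in sorted(truth.isomir_profile):
        seqs, props, _dom = truth.isomir_profile[locus]
        mean = np.full(n_samples, locus_total_mean)
        if cancer is not None and labels is not None:
            lfc = float(truth.mirna_de_effect.loc[locus, cancer])
            tumor_mask = (labels.reindex(sample_names) == "tumor").to_numpy()
            mean = np.where(tumor_mask, mean * 2.0 ** lfc, mean)
        totals = _nb_draw(rng, mean, dispersion)
        counts = np.vstack([rng.multinomial(t, props) for t in totals])  # samples x isomirs
        for i, seq in enumerate(seqs):
            rows.append([locus, seq] + list(counts[:, i]))
    return pd.DataFrame(rows, columns=["locus", "sequence"] + list(sample_names))


def generate_drug_response(
    truth: PlantedTruth,
    group_labels: pd.Series,
    pair_key: tuple[str, str],
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample x drug response matrix on a min-max-normalized [0, 1] scale.

    response ~ Normal(mu_drug + shift * I(group in {MM, AA}), noise_sd),
    truncated to [0, 1]; the shift applies only to (pair, drug) entries
    planted in truth.drug_effects for *pair_key*.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = child_rng(truth.seed, "drugs", seed)
    drugs = sorted({d for (_, d) in truth.drug_effects} | {f"D{i:02d}" for i in range(8)})
    mu = {d: rng.uniform(0.3, 0.7) for d in drugs}
    extreme = group_labels.isin(["MM", "AA"]).to_numpy()
    data = {}
    for d in drugs:
        shift = truth.drug_effects.get((pair_key, d), 0.0)
        vals = rng.normal(mu[d] + shift * extreme, noise_sd)
        data[d] = np.clip(vals, 0.0, 1.0)
    return pd.DataFrame(data, index=group_labels.index)
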