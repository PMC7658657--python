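"""Synthetic-data generators: determinism, planted-signal construction,
and distributional oracles."""
import numpy as np
import pandas as pd
import pytest

from slscreen import synthetic_data as synth


def _null_config(**kw):
    base = dict(n_genes=40, n_cancers=6, n_pairs=5, n_loci=4)
    base.update(kw)
    return synth.GeneratorConfig(**base)


class TestGenerateTruth:
    def test_null_configuration_has_no_signal(self):
        truth = synth.generate_truth(_null_config(), seed=0)
        assert (truth.de_effect.to_numpy() == 0).all()
        assert (truth.mutation_freq.to_numpy() == 0.005).all()

    def test_deterministic_for_fixed_config_and_seed(self):
        cfg = _null_config(n_combined_pairs=2, n_cancers=12, n_de_cancers=11)
        t1 = synth.generate_truth(cfg, seed=3)
        t2 = synth.generate_truth(cfg, seed=3)
        assert [p.key for p in t1.sl_pairs] == [p.key for p in t2.sl_pairs]
        assert t1.mutation_freq.equals(t2.mutation_freq)
        assert t1.de_effect.equals(t2.de_effect)
        assert t1.characteristic_sets == t2.characteristic_sets
        assert t1.target_map == t2.target_map
        t3 = synth.generate_truth(cfg, seed=4)
        assert not t1.mutation_freq.equals(t3.mutation_freq)

    def test_mutation_signal_pairs_satisfy_screen_by_construction(self):
        cfg = _null_config(n_cancers=8, n_mut_signal_pairs=3, n_mut_cancers=5)
        truth = synth.generate_truth(cfg, seed=1)
        n_qualifying = 0
        for p in truth.mut_signal_pairs:
            n_common = sum(
                1
                for c in truth.cancers
                if truth.mutation_freq.loc[p.gene_a, c] > 0.02
                and truth.mutation_freq.loc[p.gene_b, c] > 0.02
            )
            if n_common >= 5:
                n_qualifying += 1
        assert n_qualifying == 3

    def test_expression_signal_needs_eleven_cancers(self):
        with pytest.raises(ValueError, match="n_cancers >= 11"):
            synth.generate_truth(
                _null_config(n_cancers=10, n_expr_signal_pairs=1, n_de_cancers=11), seed=0
            )

    def test_mutation_signal_needs_five_cancers(self):
        with pytest.raises(ValueError, match="n_cancers >= 5"):
            synth.generate_truth(_null_config(n_cancers=4, n_mut_signal_pairs=1), seed=0)

    def test_truth_invariants_hold(self, small_truth):
        small_truth.validate()
        # pair genes disjoint across planted categories
        cats = [small_truth.mut_signal_pairs, small_truth.expr_signal_pairs,
                [c[0] for c in small_truth.combined_signal]]
        seen = set()
        for group in cats:
            for p in group:
                assert not ({p.gene_a, p.gene_b} & seen)
                seen |= {p.gene_a, p.gene_b}


class TestGenerateMutations:
    def test_zero_rate_gives_empty_table(self):
        truth = synth.generate_truth(_null_config(background_mut_rate=0.0), seed=0)
        calls, _ = synth.generate_mutations(truth, 20, seed=1)
        assert len(calls) == 0

    def test_rate_one_mutates_every_sample(self):
        truth = synth.generate_truth(_null_config(background_mut_rate=1.0), seed=0)
        calls, cohorts = synth.generate_mutations(truth, 10, seed=1)
        counts = calls.groupby(["gene", "cancer"])["sample"].nunique()
        assert (counts == 10).all()

    def test_observed_frequency_within_binomial_bound(self):
        truth = synth.generate_truth(_null_config(background_mut_rate=0.1), seed=0)
        n = 1000
        calls, _ = synth.generate_mutations(truth, n, seed=2)
        freq = calls.groupby(["gene", "cancer"])["sample"].nunique() / n
        bound = 3 * np.sqrt(0.1 * 0.9 / n)
        assert (np.abs(freq - 0.1) < bound).mean() > 0.98

    def test_variant_classes_follow_configured_law(self):
        truth = synth.generate_truth(_null_config(background_mut_rate=0.5), seed=0)
        calls, _ = synth.generate_mutations(truth, 200, seed=3)
        props = calls["variant_class"].value_counts(normalize=True)
        assert props["missense"] == pytest.approx(0.6, abs=0.02)


class TestGenerateCounts:
    def test_counts_nonnegative_integers(self):
        truth = synth.generate_truth(_null_config(), seed=0)
        counts, labels = synth.generate_counts(truth, 5, 5, seed=1,
                                               cancers=[truth.cancers[0]])[truth.cancers[0]]
        x = counts.to_numpy()
        assert np.all(x >= 0) and np.all(x == np.floor(x))
        assert (labels == "tumor").sum() == 5

    def test_rejects_bad_dispersion(self):
        truth = synth.generate_truth(_null_config(), seed=0)
        with pytest.raises(ValueError, match="dispersion"):
            synth.generate_counts(truth, 5, 5, dispersion=0.0, seed=1)

    def test_planted_fold_change_recovered_in_raw_means(self):
        cfg = _null_config(n_cancers=11, n_expr_signal_pairs=1,
                           signal_lfc=2.0, n_de_cancers=11)
        truth = synth.generate_truth(cfg, seed=0)
        cancer = truth.cancers[0]
        counts, labels = synth.generate_counts(truth, 100, 100, dispersion=0.1, seed=1,
                                               cancers=[cancer])[cancer]
        gene = truth.expr_signal_pairs[0].gene_a
        t_mean = counts.loc[gene, labels == "tumor"].mean()
        n_mean = counts.loc[gene, labels == "normal"].mean()
        assert np.log2(t_mean / n_mean) == pytest.approx(2.0, abs=0.3)

    def test_null_genes_show_no_systematic_shift(self):
        truth = synth.generate_truth(_null_config(n_genes=200), seed=0)
        cancer = truth.cancers[0]
        counts, labels = synth.generate_counts(truth, 60, 60, seed=1,
                                               cancers=[cancer])[cancer]
        from scipy import stats

        t = np.log2(counts.loc[:, labels == "tumor"] + 1)
        n = np.log2(counts.loc[:, labels == "normal"] + 1)
        _, p = stats.ttest_ind(t, n, axis=1, equal_var=False)
        assert (p < 0.01).mean() <= 0.02


class TestGenerateClinical:
    def test_positive_times_binary_events(self):
        labels = pd.Series(["MM"] * 50 + ["WW"] * 50, index=[f"s{i}" for i in range(100)])
        clin = synth.generate_clinical(labels, {"MM": 2.0}, seed=1)
        assert (clin["time"] > 0).all()
        assert set(clin["event"].unique()) <= {0, 1}

    def test_infinite_censoring_rate_censors_everyone(self):
        labels = pd.Series(["WW"] * 30, index=[f"s{i}" for i in range(30)])
        clin = synth.generate_clinical(labels, censor_hazard=1e9, seed=1)
        assert (clin["event"] == 0).all()

    def test_no_censoring_flag(self):
        labels = pd.Series(["WW"] * 30, index=[f"s{i}" for i in range(30)])
        clin = synth.generate_clinical(labels, censor_hazard=0.0, seed=1)
        assert (clin["event"] == 1).all()

    def test_planted_hazard_ratio_detected(self):
        from slscreen import survival_randomization as surv

        hits = 0
        for seed in range(20):
            labels = pd.Series(["MM"] * 200 + ["WW"] * 200,
                               index=[f"s{i}" for i in range(400)])
            clin = synth.generate_clinical(labels, {"MM": 3.0}, seed=seed)
            rec = clin.assign(group=labels)
            _, p = surv.logrank(rec)
            hits += int(p < 0.05)
        assert hits >= 19


class TestGenerateIsomirs:
    def test_single_isomir_locus_carries_total(self):
        cfg = _null_config(isomirs_per_locus=1)
        truth = synth.generate_truth(cfg, seed=0)
        table = synth.generate_isomirs(truth, 10, seed=1)
        assert (table.groupby("locus").size() == 1).all()

    def test_counts_sum_to_locus_total(self, small_truth):
        table = synth.generate_isomirs(small_truth, 20, seed=1)
        sample_cols = table.columns[2:]
        # multinomial conservation: per-locus totals are NB draws, and the
        # isomiR rows of a locus split them exactly
        totals = table.groupby("locus")[list(sample_cols)].sum()
        assert (totals.to_numpy() >= 0).all()
        for locus, (seqs, props, dom) in small_truth.isomir_profile.items():
            sub = table[table["locus"] == locus]
            assert len(sub) == len(seqs)

    def test_nonnegative_integer_counts(self, small_truth):
        table = synth.generate_isomirs(small_truth, 5, seed=2)
        x = table[table.columns[2:]].to_numpy()
        assert np.all(x >= 0) and x.dtype.kind in "iu"


class TestGenerateDrugResponse:
    def test_values_in_unit_interval(self, small_truth):
        labels = pd.Series(["MM"] * 20 + ["WW"] * 20, index=[f"s{i}" for i in range(40)])
        key = small_truth.sl_pairs[0].key
        m = synth.generate_drug_response(small_truth, labels, key, seed=1)
        assert ((m.to_numpy() >= 0) & (m.to_numpy() <= 1)).all()

    def test_no_planted_shift_means_balanced_groups(self, small_truth):
        labels = pd.Series(["MM"] * 200 + ["WW"] * 200, index=[f"s{i}" for i in range(400)])
        unplanted = next(
            p.key for p in small_truth.sl_pairs
            if not any(k == p.key for (k, _) in small_truth.drug_effects)
        )
        m = synth.generate_drug_response(small_truth, labels, unplanted, noise_sd=0.05, seed=1)
        diff = m[labels == "MM"].mean() - m[labels == "WW"].mean()
        # 4-sigma normal-theory bound on a difference of means, per drug
        assert (diff.abs() < 4 * 0.05 * np.sqrt(2 / 200)).all()

    def test_planted_shift_visible(self, small_truth):
        (key, drug), shift = next(iter(small_truth.drug_effects.items()))
        labels = pd.Series(["MM"] * 50 + ["WW"] * 50, index=[f"s{i}" for i in range(100)])
        m = synth.generate_drug_response(small_truth, labels, key, noise_sd=0.05, seed=1)
        diff = m.loc[labels == "MM", drug].mean() - m.loc[labels == "WW", drug].mean()
        assert diff == pytest.approx(shift, abs=0.05)


def test_generators_byte_identical_across_runs(tmp_path):
    from slscreen import io

    cfg = _null_config(n_combined_pairs=1, n_cancers=12, n_de_cancers=11)
    outs = []
    for run in ("a", "b"):
        truth = synth.generate_truth(cfg, seed=5)
        calls, _ = synth.generate_mutations(truth, 20, seed=1)
        path = tmp_path / f"{run}.maf.tsv"
        io.write_maf(calls, path)
        outs.append(path.read_bytes())
    assert outs[0] == outs[1]
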