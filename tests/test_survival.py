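"""Kaplan-Meier, log-rank, prognostic scan, and the randomization test."""
import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from slscreen import survival_randomization as surv, synthetic_data as synth
from slscreen._types import RandomizationResult, canonical_pair


class TestKmEstimate:
    def test_no_events_flat_at_one(self):
        km = surv.km_estimate([5, 8, 13], [0, 0, 0])
        assert km["survival"].tolist() == [1.0]

    def test_two_event_closed_form(self):
        km = surv.km_estimate([1, 2], [1, 1])
        assert km["survival"].tolist() == [1.0, 0.5, 0.0]

    def test_matches_lifelines(self, rng):
        t = rng.exponential(100, 60)
        e = (rng.random(60) < 0.7).astype(int)
        km = surv.km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for time, s in zip(km["time"], km["survival"]):
            assert kmf.predict(time) == pytest.approx(s, abs=1e-10)

    def test_nonincreasing_and_starts_at_one(self, rng):
        for _ in range(10):
            t = rng.exponential(50, 30)
            e = rng.integers(0, 2, 30)
            km = surv.km_estimate(t, e)
            assert km["survival"].iloc[0] == 1.0
            assert np.all(np.diff(km["survival"]) <= 1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            surv.km_estimate([], [])


class TestLogrank:
    def _records(self, times, events, groups):
        return pd.DataFrame({"time": times, "event": events, "group": groups})

    def test_identical_groups_give_zero_statistic(self):
        rec = self._records([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0], list("AAABBB"))
        stat, p = surv.logrank(rec)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_sample_example(self):
        # group A events at 1, 2; group B events at 3, 4; direct O-E sums:
        # t=1: d=1 nA=2 nB=2 -> eA=0.5 vA=0.25
        # t=2: d=1 nA=1 nB=2 -> eA=1/3 vA=2/9
        # t=3: d=1 nA=0 nB=2 -> eA=0   vA=0
        # t=4: d=1 nA=0 nB=1 -> eA=0   vA=0
        # O_A=2, E_A=5/6, V=0.25+2/9 -> chi2 = (2-5/6)^2/V
        rec = self._records([1, 2, 3, 4], [1, 1, 1, 1], list("AABB"))
        stat, _ = surv.logrank(rec)
        expected = (2 - 5 / 6) ** 2 / (0.25 + 2 / 9)
        assert stat == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_lifelines_on_random_instances(self, rng, k):
        for _ in range(25):
            n = int(rng.integers(20, 80))
            t = rng.exponential(100, n).round(1) + 0.1  # force ties
            e = (rng.random(n) < 0.7).astype(int)
            g = rng.integers(0, k, n)
            if len(np.unique(g)) < k:
                continue
            rec = self._records(t, e, [chr(65 + x) for x in g])
            stat, p = surv.logrank(rec)
            ref = multivariate_logrank_test(t, g, e)
            assert stat == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_single_group_rejected(self):
        rec = self._records([1, 2], [1, 1], ["A", "A"])
        with pytest.raises(ValueError, match="at least 2"):
            surv.logrank(rec)

    def test_null_pvalues_uniform(self):
        # calibration: under HR = 1 the p-value is Uniform(0, 1)
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(500):
            t = rng.exponential(100, 60)
            e = (rng.random(60) < 0.7).astype(int)
            g = np.repeat([0, 1], 30)
            eng = surv.LogrankEngine(t, e)
            pvals.append(eng.test(g, 2)[1])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPairScan:
    def _setup(self, rng, n=120, hr=1.0):
        genes = [f"G{i}" for i in range(10)]
        samples = [f"s{i}" for i in range(n)]
        flags = pd.DataFrame(
            rng.random((10, n)) < 0.4, index=genes, columns=samples
        )
        pairs = [canonical_pair(genes[i], genes[i + 1]) for i in range(0, 10, 2)]
        groupings = {}
        for a, b in pairs:
            fa, fb = flags.loc[a], flags.loc[b]
            groupings[(a, b)] = pd.Series(
                np.where(fa & fb, "MM", np.where(~fa & ~fb, "WW", "MW")), index=samples
            )
        mult = pd.Series(1.0, index=samples)
        mm = groupings[pairs[0]] == "MM"
        mult[mm] = hr
        clinical = synth.generate_clinical(
            pd.Series("WW", index=samples), hazard_multiplier=mult, seed=int(rng.integers(2**31))
        )
        return pairs, groupings, clinical

    def test_null_counts_near_alpha(self, rng):
        counts = []
        for _ in range(40):
            pairs, groupings, clinical = self._setup(rng)
            _, c = surv.pair_prognostic_scan(pairs, groupings, clinical, "two_group")
            counts.append(c)
        # 200 pair tests at alpha 0.05 -> expect ~10 significant
        assert 1 <= sum(counts) <= 25

    def test_planted_hazard_detected(self, rng):
        hits = 0
        for _ in range(10):
            pairs, groupings, clinical = self._setup(rng, n=400, hr=3.0)
            table, _ = surv.pair_prognostic_scan(pairs, groupings, clinical, "two_group")
            row = table[(table["gene_a"] == pairs[0][0]) & (table["gene_b"] == pairs[0][1])]
            hits += int(row["pvalue"].iloc[0] < 0.05)
        assert hits >= 9

    def test_small_groups_skipped(self, rng):
        pairs, groupings, clinical = self._setup(rng, n=20)
        key = pairs[0]
        groupings[key][:] = "MW"
        groupings[key].iloc[0] = "MM"
        table, _ = surv.pair_prognostic_scan(pairs, groupings, clinical, "two_group")
        row = table[(table["gene_a"] == key[0]) & (table["gene_b"] == key[1])]
        assert not row["tested"].iloc[0]

    def test_empty_pair_list_counts_zero(self, rng):
        _, _, clinical = self._setup(rng)
        table, count = surv.pair_prognostic_scan([], {}, clinical, "two_group")
        assert count == 0 and len(table) == 0

    def test_three_group_scheme_uses_all_groups(self, rng):
        pairs, groupings, clinical = self._setup(rng, n=300)
        table, _ = surv.pair_prognostic_scan(pairs, groupings, clinical, "three_group")
        assert table["tested"].any()


class TestEmpiricalP:
    def test_definition_example(self):
        r = RandomizationResult(2.0, np.array([1.0, 5.0, 2.0, 0.0]), 0.5, 4, 0, "two_group")
        assert np.mean(r.null_stats >= r.observed_stat) == 0.5

    def test_observed_above_all_nulls_gives_zero(self, rng):
        genes = [f"G{i}" for i in range(30)]
        samples = [f"s{i}" for i in range(60)]
        flags = pd.DataFrame(rng.random((30, 60)) < 0.4, index=genes, columns=samples)

        def builder(key):
            fa, fb = flags.loc[key[0]], flags.loc[key[1]]
            return pd.Series(
                np.where(fa & fb, "MM", np.where(~fa & ~fb, "WW", "MW")), index=samples
            )

        clinical = synth.generate_clinical(pd.Series("WW", index=samples), seed=5)
        observed = [canonical_pair("G0", "G1")]
        result = surv.randomization_test(
            observed, genes, set(observed), clinical, builder, B=20, seed=3
        )
        assert result.empirical_p == np.mean(result.null_stats >= result.observed_stat)
        assert len(result.null_stats) == 20

    def test_fixed_seed_reproducible(self, rng):
        genes = [f"G{i}" for i in range(20)]
        samples = [f"s{i}" for i in range(50)]
        flags = pd.DataFrame(rng.random((20, 50)) < 0.4, index=genes, columns=samples)

        def builder(key):
            fa, fb = flags.loc[key[0]], flags.loc[key[1]]
            return pd.Series(
                np.where(fa & fb, "MM", np.where(~fa & ~fb, "WW", "MW")), index=samples
            )

        clinical = synth.generate_clinical(pd.Series("WW", index=samples), seed=5)
        observed = [canonical_pair("G0", "G1")]
        r1 = surv.randomization_test(observed, genes, set(observed), clinical, builder, B=10, seed=9)
        r2 = surv.randomization_test(observed, genes, set(observed), clinical, builder, B=10, seed=9)
        assert np.array_equal(r1.null_stats, r2.null_stats)
        assert r1.empirical_p == r2.empirical_p

    def test_universe_too_small_rejected(self, rng):
        clinical = synth.generate_clinical(pd.Series("WW", index=["s1", "s2"]), seed=1)
        observed = [canonical_pair("A", "B")]
        with pytest.raises(ValueError, match="universe"):
            surv.randomization_test(
                observed, ["A", "B"], {("A", "B")}, clinical, lambda k: None, B=2, seed=0
            )

    def test_sampled_pairs_avoid_excluded(self, rng):
        genes = [f"G{i}" for i in range(8)]
        excluded = {canonical_pair("G0", "G1"), canonical_pair("G2", "G3")}
        g = np.random.default_rng(0)
        for _ in range(20):
            pairs = surv.sample_random_pairs(g, genes, 5, excluded)
            assert len(pairs) == 5 and len(set(pairs)) == 5
            assert not (set(pairs) & excluded)
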