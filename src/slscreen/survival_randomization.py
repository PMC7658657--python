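"""Kaplan-Meier estimation, k-sample log-rank tests, and the empirical
randomization test for prognostic enrichment of synthetic-lethal pairs.

The randomization test asks whether the number of SL pairs whose patient
grouping (MM/MW/WW or AA/AN/NN) separates survival at p < alpha exceeds
what equally many random, non-SL gene pairs achieve; the empirical p is
the plain proportion of B null draws with a count at least as large as
the observed one.

The log-rank statistic is computed by a vectorized in-house routine
(``LogrankEngine``) because the randomization test evaluates it tens of
thousands of times per run; it matches the classical k-sample chi-square
(lifelines' ``multivariate_logrank_test``) to numerical precision.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._types import RandomizationResult, canonical_pair

log = logging.getLogger(__name__)

#: Extreme ("double-letter") groups used by the two-group scheme.
EXTREME_GROUPS = {"MM", "WW", "AA", "NN"}
MIDDLE_GROUPS = {"MW", "AN"}


# ---------------------------------------------------------------------------
# Kaplan-Meier

def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step function as a DataFrame (time, survival) starting at
    (0, 1); survival is nonincreasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty group")
    if np.any(times <= 0):
        raise ValueError("survival times must be strictly positive")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, starts = np.unique(t, return_index=True)
    d = np.add.reduceat(e, starts)
    n_at_risk = t.size - starts
    keep = d > 0
    surv = np.cumprod(1.0 - d[keep] / n_at_risk[keep])
    return pd.DataFrame(
        {"time": np.concatenate([[0.0], uniq[keep]]), "survival": np.concatenate([[1.0], surv])}
    )


def km_by_group(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """KM estimate per group of a (time, event, group) records table."""
    return {
        g: km_estimate(sub["time"].to_numpy(), sub["event"].to_numpy())
        for g, sub in records.groupby("group")
    }


# ---------------------------------------------------------------------------
# log-rank

class LogrankEngine:
    """Pre-sorted cohort for repeated k-sample log-rank evaluation.

    Sorting and event-time segmentation of the cohort are done once; each
    call to :meth:`test` with a fresh group-code vector is then linear in
    the cohort size.
    """

    def __init__(self, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if np.any(times <= 0):
            raise ValueError("survival times must be strictly positive")
        self.n = times.size
        self.order = np.argsort(times, kind="stable")
        t = times[self.order]
        self.events_sorted = events[self.order]
        _, self.starts = np.unique(t, return_index=True)
        self.d_total = np.add.reduceat(self.events_sorted, self.starts)
        self.n_at_risk = self.n - self.starts
        # only event times contribute
        self._ev = self.d_total > 0

    def test(self, group_codes, k: int) -> tuple[float, float, int]:
        """k-sample log-rank chi-square for one grouping.

        *group_codes*: integer array (0..k-1, or -1 for samples excluded
        from the contrast), aligned with the times/events passed to the
        constructor.  Returns (statistic, p, df).  Groups with no members
        are dropped; fewer than 2 usable groups is an error.
        """
        g = np.asarray(group_codes)[self.order]
        present = [j for j in range(k) if np.any(g == j)]
        if len(present) < 2:
            raise ValueError("log-rank needs at least 2 nonempty groups")
        if len(present) < k:
            log.warning("log-rank: dropping %d empty group(s)", k - len(present))
        kk = len(present)
        nblocks = self.starts.size
        D = np.empty((kk, nblocks))  # events per group per time block
        A = np.empty((kk, nblocks))  # at-risk per group per time block
        for jj, j in enumerate(present):
            ind = (g == j).astype(np.int64)
            csum = np.concatenate([[0], np.cumsum(ind)])
            A[jj] = csum[-1] - csum[self.starts]
            D[jj] = np.add.reduceat(ind * self.events_sorted, self.starts)
        # restrict everything to the samples in the contrast (codes >= 0)
        d = D.sum(axis=0)
        nb = A.sum(axis=0)
        ok = (d > 0) & (nb > 0)
        d, nb, A = d[ok], nb[ok], A[:, ok]
        O = D[:, ok].sum(axis=1)
        if d.size == 0:
            return 0.0, 1.0, kk - 1
        frac = A / nb
        E = (d * frac).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(nb > 1, d * (nb - d) / (nb - 1), 0.0)
        V = -np.einsum("b,jb,lb->jl", c, frac, frac)
        V[np.diag_indices(kk)] += (c * frac).sum(axis=1)
        z = (O - E)[:-1]
        Vr = V[:-1, :-1]
        try:
            stat = float(z @ np.linalg.solve(Vr, z))
        except np.linalg.LinAlgError:
            stat = float(z @ np.linalg.pinv(Vr) @ z)
        stat = max(stat, 0.0)
        df = kk - 1
        return stat, float(stats.chi2.sf(stat, df)), df


def logrank(records: pd.DataFrame, k_groups: int | None = None) -> tuple[float, float]:
    """k-sample log-rank test on a (time, event, group) records table.

    Returns (chi-square statistic, two-sided p from the chi-square tail
    with k-1 df).
    """
    labels = sorted(records["group"].unique())
    if k_groups is not None and len(labels) != k_groups:
        log.warning("expected %d groups, found %d", k_groups, len(labels))
    if len(labels) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    codes = records["group"].map({lab: i for i, lab in enumerate(labels)}).to_numpy()
    engine = LogrankEngine(records["time"].to_numpy(), records["event"].to_numpy())
    stat, p, _ = engine.test(codes, len(labels))
    return stat, p


# ---------------------------------------------------------------------------
# per-pair scan

def _codes_for_scheme(groups: pd.Series, scheme: str) -> tuple[np.ndarray, int, dict[str, int]]:
    """Map group labels to integer codes for the chosen scheme.

    two_group keeps only the extreme groups (MM vs WW, AA vs NN); middle
    samples get code -1 and are excluded.  three_group uses all three.
    """
    labels = set(groups.unique())
    if scheme == "two_group":
        keep = sorted(labels & EXTREME_GROUPS)
        mapping = {lab: i for i, lab in enumerate(keep)}
        k = 2
    elif scheme == "three_group":
        ordered = [lab for lab in ("MM", "MW", "WW", "AA", "AN", "NN") if lab in labels]
        mapping = {lab: i for i, lab in enumerate(ordered)}
        k = 3
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    codes = groups.map(mapping).fillna(-1).astype(np.int64).to_numpy()
    return codes, k, mapping


def _scheme_family(groups: pd.Series) -> tuple[str, ...]:
    """The full label triple a grouping belongs to (mutation or expression)."""
    labels = set(groups.dropna().unique())
    if labels <= {"MM", "MW", "WW"}:
        return ("MM", "MW", "WW")
    if labels <= {"AA", "AN", "NN"}:
        return ("AA", "AN", "NN")
    raise ValueError(f"mixed or unknown group labels: {sorted(labels)}")


def pair_prognostic_scan(
    pairs,
    groupings: dict,
    clinical: pd.DataFrame,
    scheme: str = "two_group",
    alpha: float = 0.05,
    min_group: int = 5,
    engine: LogrankEngine | None = None,
) -> tuple[pd.DataFrame, int]:
    """Log-rank test for every pair's grouping; counts significant pairs.

    *groupings* maps pair key -> per-sample group label Series;
    *clinical* is indexed by sample with columns time, event.  Pairs with
    any required group smaller than *min_group* are skipped (logged) and
    do not enter the count.  Returns the per-pair table and
    count = |{tested pairs with p < alpha}|.
    """
    if engine is None:
        engine = LogrankEngine(clinical["time"].to_numpy(), clinical["event"].to_numpy())
    rows = []
    count = 0
    for pair in pairs:
        key = pair.key if hasattr(pair, "key") else canonical_pair(*pair)
        groups = groupings[key].reindex(clinical.index)
        codes, k, mapping = _codes_for_scheme(groups, scheme)
        family = _scheme_family(groups)
        required = (family[0], family[2]) if scheme == "two_group" else family
        sizes = groups.value_counts()
        usable = all(sizes.get(lab, 0) >= min_group for lab in required)
        if not usable:
            log.info("pair %s skipped: group sizes %s below %d", key, sizes.to_dict(), min_group)
            rows.append((key[0], key[1], scheme, str(sizes.to_dict()), np.nan, np.nan, False))
            continue
        stat, p, _ = engine.test(codes, k)
        significant = p < alpha
        count += int(significant)
        rows.append((key[0], key[1], scheme, str(sizes.to_dict()), stat, p, True))
    table = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "scheme", "group_sizes", "statistic", "pvalue", "tested"]
    )
    return table, count


# ---------------------------------------------------------------------------
# randomization test

def sample_random_pairs(
    rng: np.random.Generator,
    gene_universe: list[str],
    n_pairs: int,
    excluded: set[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Uniform sample of *n_pairs* distinct unordered gene pairs from the
    universe, avoiding the excluded set (the SL catalog)."""
    n = len(gene_universe)
    total = n * (n - 1) // 2
    universe = set(gene_universe)
    n_excluded_in = sum(1 for (a, b) in excluded if a in universe and b in universe)
    if total - n_excluded_in < n_pairs:
        raise ValueError(
            f"universe of {n} genes cannot supply {n_pairs} pairs outside the excluded set"
        )
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < n_pairs:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        key = canonical_pair(gene_universe[i], gene_universe[j])
        if key in excluded or key in chosen:
            continue
        chosen.add(key)
    return sorted(chosen)


def randomization_test(
    observed_pairs,
    gene_universe: list[str],
    excluded_pairs: set,
    clinical: pd.DataFrame,
    groupings_builder,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "two_group",
    alpha: float = 0.05,
    min_group: int = 5,
    statistic: str = "count",
    plus_one: bool = False,
) -> RandomizationResult:
    """Empirical randomization test for prognostic enrichment.

    Each of B iterations draws |observed_pairs| random unordered pairs
    from *gene_universe* (excluding *excluded_pairs*, normally the SL
    catalog), rebuilds groupings via *groupings_builder* (pair key ->
    per-sample group Series), and recomputes the significant-pair count
    under identical thresholds.  ``statistic="mean_neglog10p"`` swaps the
    count for the mean -log10 p over tested pairs.

    empirical_p = #{null >= observed} / B by default; ``plus_one=True``
    uses (#{null >= observed} + 1) / (B + 1).
    """
    if statistic not in ("count", "mean_neglog10p"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    observed_list = list(observed_pairs)
    excluded_check = {
        p.key if hasattr(p, "key") else canonical_pair(*p) for p in excluded_pairs
    }
    n_u = len(gene_universe)
    universe_set = set(gene_universe)
    n_excl_in = sum(1 for (a, b) in excluded_check if a in universe_set and b in universe_set)
    if n_u * (n_u - 1) // 2 - n_excl_in < len(observed_list):
        raise ValueError(
            f"universe of {n_u} genes cannot supply {len(observed_list)} pairs "
            "outside the excluded set"
        )
    engine = LogrankEngine(clinical["time"].to_numpy(), clinical["event"].to_numpy())

    def _stat(pair_keys) -> float:
        groupings = {k: groupings_builder(k) for k in pair_keys}
        table, count = pair_prognostic_scan(
            pair_keys, groupings, clinical, scheme, alpha, min_group, engine=engine
        )
        if statistic == "count":
            return float(count)
        p = table.loc[table["tested"], "pvalue"].to_numpy()
        if p.size == 0:
            return 0.0
        return float(np.mean(-np.log10(np.maximum(p, 1e-300))))

    observed_keys = [
        p.key if hasattr(p, "key") else canonical_pair(*p) for p in observed_pairs
    ]
    excluded = {p.key if hasattr(p, "key") else canonical_pair(*p) for p in excluded_pairs}
    observed_stat = _stat(observed_keys)

    null_stats = np.empty(B)
    for b in range(B):
        keys = sample_random_pairs(rng, gene_universe, len(observed_keys), excluded)
        null_stats[b] = _stat(keys)

    n_ge = int(np.sum(null_stats >= observed_stat))
    empirical_p = (n_ge + 1) / (B + 1) if plus_one else n_ge / B
    return RandomizationResult(
        observed_stat=observed_stat,
        null_stats=null_stats,
        empirical_p=float(empirical_p),
        B=B,
        seed=seed,
        scheme=scheme,
        statistic=statistic,
    )
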