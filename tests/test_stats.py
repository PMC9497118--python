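"""Unit and property tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from comboscreen.stats import (bh_fdr, cox_fit, fishers_product, km_estimate,
                               wilcoxon_rank_sum)


# ---------------------------------------------------------------------------
# Oracles (independent of the implementation path)
# ---------------------------------------------------------------------------

def brute_force_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(x) + sorted(y)
    n, m = len(x), len(y)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    mu = n * (n + m + 1) / 2
    stats = []
    for comb in itertools.combinations(range(n + m), n):
        stats.append(sum(sorted(ranks.values())[i] for i in comb))
    stats = np.array(stats)
    p = np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-12)
    return float(p)


def brute_force_bh(p):
    """BH step-up from its definition: q_i = min_{j: p_(j) >= p_(i)} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j
                      for j in range(rank_pos, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def product_limit(times, events):
    """Hand-rolled Kaplan–Meier at the distinct observed times."""
    order = np.argsort(times)
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    out = {}
    s = 1.0
    for u in np.unique(t):
        at_risk = np.sum(t >= u)
        d = np.sum((t == u) & (e == 1))
        s *= (1 - d / at_risk)
        out[float(u)] = s
    return out


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

class TestCoxFit:
    def test_constant_covariate_dropped_and_fit_proceeds(self, bundles):
        bt, _ = bundles
        X = bt.clinical[["age"]].astype(float).copy()
        X["flat"] = 1.0
        fit = cox_fit(bt.clinical.os_time, bt.clinical.os_event, X)
        assert "flat" in fit.dropped_terms
        assert fit.converged and "age" in fit.p_values

    def test_quasi_constant_binary_dropped(self, bundles):
        bt, _ = bundles
        X = bt.clinical[["age"]].astype(float).copy()
        rare = np.zeros(bt.n_patients)
        rare[0] = 1.0
        X["rare"] = rare
        fit = cox_fit(bt.clinical.os_time, bt.clinical.os_event, X)
        assert "rare" in fit.dropped_terms and fit.converged

    def test_all_censored_flagged_not_raised(self, bundles):
        bt, _ = bundles
        X = bt.clinical[["age"]].astype(float)
        fit = cox_fit(bt.clinical.os_time, np.zeros(bt.n_patients), X)
        assert not fit.converged
        assert all(p == 1.0 for p in fit.p_values.values())

    def test_patient_permutation_invariance(self, bundles):
        bt, _ = bundles
        X = bt.clinical[["age", "ipi_nivo_tx"]].astype(float)
        t, e = bt.clinical.os_time.to_numpy(), bt.clinical.os_event.to_numpy()
        fit1 = cox_fit(t, e, X)
        rng = np.random.default_rng(7)
        perm = rng.permutation(bt.n_patients)
        fit2 = cox_fit(t[perm], e[perm], X.iloc[perm])
        for c in fit1.coefficients:
            assert fit1.coefficients[c] == pytest.approx(
                fit2.coefficients[c], abs=1e-10)


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_textbook_exact_value(self):
        # most extreme split of 4 values: 2 of 6 assignments as extreme
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]) == 1.0

    def test_empty_group_unavailable(self):
        assert wilcoxon_rank_sum([], [1.0, 2.0]) is None

    @pytest.mark.parametrize("n,m", [(2, 2), (3, 4), (5, 5), (6, 4), (6, 6)])
    def test_exact_matches_brute_force_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(5):
            x = rng.permutation(np.arange(1.0, n + m + 1))[:n]
            y = np.setdiff1d(np.arange(1.0, n + m + 1), x)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                brute_force_rank_sum_p(list(x), list(y)), abs=1e-12)

    def test_large_sample_matches_normal_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 120), rng.normal(0, 1, 80)
        # tie-corrected normal approximation with continuity correction
        n, m = len(x), len(y)
        allv = np.concatenate([x, y])
        ranks = sps.rankdata(allv)
        u = ranks[:n].sum() - n * (n + 1) / 2
        mu = n * m / 2
        ties = np.unique(allv, return_counts=True)[1]
        sd = math.sqrt(n * m / 12 * ((n + m + 1)
                       - np.sum(ties ** 3 - ties) / ((n + m) * (n + m - 1))))
        z = (abs(u - mu) - 0.5) / sd
        expected = 2 * sps.norm.sf(z)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# Fisher's product method
# ---------------------------------------------------------------------------

class TestFishersProduct:
    def test_all_ones_gives_zero_chi2(self):
        r = fishers_product([("a", 1.0), ("b", 1.0)])
        assert r.chi2 == 0.0 and r.df == 4 and r.p_combined == 1.0

    def test_halves_closed_form(self):
        r = fishers_product([("a", 0.5), ("b", 0.5)])
        assert r.chi2 == pytest.approx(-4 * math.log(0.5), abs=1e-4)
        assert r.p_combined == pytest.approx(0.5966, abs=1e-4)

    def test_missing_terms_shrink_df(self):
        r = fishers_product([("a", 0.1), ("b", None), ("c", 0.2)])
        assert r.df == 4 and r.terms_missing == ["b"]

    def test_impute_one_policy_keeps_df(self):
        r = fishers_product([("a", 0.1), ("b", None)], missing="impute_one")
        assert r.df == 4 and r.terms_missing == []
        assert r.chi2 == pytest.approx(-2 * math.log(0.1))

    def test_all_missing_flagged_unavailable(self):
        r = fishers_product([("a", None), ("b", float("nan"))])
        assert not r.available and math.isnan(r.p_combined)

    def test_permutation_invariant_and_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ps = rng.uniform(0.001, 1, 4)
            labeled = [(f"t{i}", p) for i, p in enumerate(ps)]
            shuffled = [labeled[i] for i in rng.permutation(4)]
            assert (fishers_product(labeled).p_combined
                    == fishers_product(shuffled).p_combined)
            smaller = [("t0", ps[0] * 0.5)] + labeled[1:]
            assert (fishers_product(smaller).p_combined
                    <= fishers_product(labeled).p_combined)

    def test_floor_prevents_infinite_chi2(self):
        r = fishers_product([("a", 0.0)])
        assert np.isfinite(r.chi2)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=10))
    def test_definition_holds_for_arbitrary_inputs(self, ps):
        r = fishers_product([(f"t{i}", p) for i, p in enumerate(ps)])
        assert r.df == 2 * len(ps)
        assert r.chi2 == pytest.approx(
            -2 * math.fsum(math.log(max(p, 1e-300)) for p in ps))
        assert 0.0 < r.p_combined <= 1.0


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_bounded_and_sorted_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 100)
        q = bh_fdr(p)
        assert q.max() <= 1.0
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

class TestKmEstimate:
    def test_three_events_product_limit(self):
        curves = km_estimate([1, 2, 3], [1, 1, 1], ["g", "g", "g"])
        df = curves["g"].set_index("time")["survival"]
        assert df[1.0] == pytest.approx(2 / 3)
        assert df[2.0] == pytest.approx(1 / 3)
        assert df[3.0] == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        curves = km_estimate([5, 10, 15], [0, 0, 0], ["g"] * 3)
        assert np.allclose(curves["g"]["survival"], 1.0)

    def test_matches_hand_rolled_oracle_on_random_fixture(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 100).round(2) + 0.01
        e = rng.integers(0, 2, 100)
        curves = km_estimate(t, e, ["g"] * 100)
        oracle = product_limit(t, e)
        got = curves["g"].set_index("time")["survival"]
        for u, s in oracle.items():
            assert got[u] == pytest.approx(s, abs=1e-10)

    def test_survival_non_increasing_starts_at_one(self):
        rng = np.random.default_rng(4)
        curves = km_estimate(rng.exponential(5, 50) + 0.1,
                             rng.integers(0, 2, 50),
                             rng.choice(["a", "b"], 50))
        for df in curves.values():
            s = df["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert np.all(np.diff(s) <= 1e-12)

    def test_unknown_group_label_fatal(self):
        with pytest.raises(ValueError, match="unknown group"):
            km_estimate([1, 2], [1, 1], ["a", "b"], groups=["a"])
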