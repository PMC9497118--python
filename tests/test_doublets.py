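"""Doublet enumeration, model terms, and the three combination methods."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from comboscreen.doublets import (DoubletConfig, combine_method1,
                                  combine_method2, combine_method3,
                                  doublet_table, enumerate_doublets,
                                  fit_doublet_models, filter_subgroup,
                                  run_subgroup, score_doublet, TERM_NAMES)
from comboscreen.simulate import EffectSpec, SimulationConfig, simulate_cohorts

from conftest import make_bundle, make_library


def _terms(t_vals=None, m_vals=None):
    """Build the terms structure; unspecified terms default to None."""
    out = {}
    for c, vals in (("t", t_vals), ("m", m_vals)):
        out[c] = {k: None for k in TERM_NAMES}
        if vals:
            out[c].update(vals)
    return out


def _full(p):
    return {k: p for k in TERM_NAMES}


class TestEnumerate:
    def test_three_seeds_pool_five(self):
        pool = ["a", "b", "c", "d", "e"]
        dp = enumerate_doublets(["a", "b", "c"], pool)
        assert len(dp.pairs) == 9
        assert dp.n_seed_seed == 3 and dp.n_seed_other == 6

    def test_single_seed_closed_form(self):
        pool = [f"d{i}" for i in range(12)]
        dp = enumerate_doublets(["d0"], pool)
        assert len(dp.pairs) == 11

    def test_all_seeds_combinations(self):
        pool = [f"d{i}" for i in range(7)]
        dp = enumerate_doublets(pool, pool)
        assert len(dp.pairs) == math.comb(7, 2)

    def test_no_self_or_duplicate_pairs(self):
        dp = enumerate_doublets(["a", "b"], ["a", "b", "c"])
        assert all(p[0] < p[1] for p in dp.pairs)
        assert len(set(dp.pairs)) == len(dp.pairs)

    def test_empty_seeds_fatal(self):
        with pytest.raises(ValueError):
            enumerate_doublets([], ["a"])


class TestFitDoubletModels:
    def test_zero_mutation_drug_yields_missing_terms(self):
        mut = pd.DataFrame(
            np.array([[1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
                      [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]],
                     dtype=np.int8),
            index=["A", "B"], columns=[f"t_p{i}" for i in range(15)])
        bundle = make_bundle(n=15, genes=("A", "B"), mutations=mut, seed=5)
        lib = make_library({"d1": ["A"], "d2": ["B"]})
        terms, flags = fit_doublet_models(("d1", "d2"), bundle, lib)
        assert terms["pM2"] is None and terms["pM3"] is None
        assert terms["pQ2"] is None
        assert terms["pE1"] is not None and terms["pE2"] is not None

    def test_patient_permutation_invariance(self, bundles, library):
        bt, _ = bundles
        pair = tuple(library.drugs[:2])
        t1, _ = fit_doublet_models(pair, bt, library)
        rng = np.random.default_rng(3)
        perm = list(rng.permutation(bt.patients))
        t2, _ = fit_doublet_models(pair, bt.subset(perm), library)
        for k in TERM_NAMES:
            if t1[k] is None:
                assert t2[k] is None
            else:
                assert t1[k] == pytest.approx(t2[k], abs=1e-8)

    def test_overlapping_targets_flagged(self, bundles):
        bt, _ = bundles
        genes = list(bt.mutations.index[:4])
        lib = make_library({"d1": genes[:3], "d2": genes[1:4]})
        _, flags = fit_doublet_models(("d1", "d2"), bt, lib)
        assert any(f.startswith("target_overlap") for f in flags)


class TestMethod1:
    def test_all_ones_full_df(self):
        r = combine_method1(_terms(_full(1.0), _full(1.0)))
        assert r.df == 32 and r.p_combined == 1.0

    def test_all_halves_closed_form(self):
        r = combine_method1(_terms(_full(0.5), _full(0.5)))
        assert r.chi2 == pytest.approx(-2 * 16 * math.log(0.5), abs=1e-3)
        assert r.p_combined == pytest.approx(
            sps.chi2.sf(-32 * math.log(0.5), 32), abs=1e-10)

    def test_missing_terms_reduce_df(self):
        t_vals = _full(0.3)
        for k in ("pM3", "pQ1", "pQ2"):
            t_vals[k] = None
        r = combine_method1(_terms(t_vals, _full(0.3)))
        assert r.df == 26
        expect = -2 * 13 * math.log(0.3)
        assert r.chi2 == pytest.approx(expect, abs=1e-9)


class TestMethod2:
    def test_pass_filter_all_below_alpha(self):
        terms = _terms({"pE1": 0.04, "pE2": 0.03}, {"pE1": 0.02, "pE2": 0.01})
        r, ok = combine_method2(terms)
        assert ok
        expect = -2 * math.fsum(math.log(p) for p in (0.04, 0.03, 0.02, 0.01))
        assert r.chi2 == pytest.approx(expect)
        assert r.p_combined == pytest.approx(sps.chi2.sf(expect, 8), abs=1e-12)

    def test_filter_fails_on_one_above_alpha(self):
        terms = _terms({"pE1": 0.04, "pE2": 0.06}, {"pE1": 0.02, "pE2": 0.01})
        _, ok = combine_method2(terms)
        assert not ok

    def test_missing_term_fails_filter_and_shrinks_df(self):
        terms = _terms({"pE1": 0.04}, {"pE1": 0.02, "pE2": 0.01})
        r, ok = combine_method2(terms)
        assert not ok and r.df == 6

    def test_uses_only_expression_main_effects(self):
        # wildly significant mutation terms must not move method 2
        base = _terms({"pE1": 0.5, "pE2": 0.5}, {"pE1": 0.5, "pE2": 0.5})
        loud = _terms({"pE1": 0.5, "pE2": 0.5, "pM1": 1e-30},
                      {"pE1": 0.5, "pE2": 0.5, "pM3": 1e-30})
        assert (combine_method2(base)[0].p_combined
                == combine_method2(loud)[0].p_combined)


class TestMethod3:
    def test_different_families_uses_minima(self):
        terms = _terms(
            {"pM1": 0.5, "pE1": 0.01, "pQ1": 0.4},
            {"pM1": 0.02, "pE1": 0.6, "pQ2": 0.3})
        r = combine_method3(terms)
        assert r.df == 4
        expect = -2 * (math.log(0.01) + math.log(0.02))
        assert r.chi2 == pytest.approx(expect)

    def test_same_cox_family_substitutes_interaction(self):
        terms = _terms(
            {"pM1": 0.01, "pM3": 0.2, "pE1": 0.5},
            {"pM2": 0.03, "pM3": 0.4, "pE1": 0.6})
        r = combine_method3(terms)
        expect = -2 * (math.log(0.2) + math.log(0.4))
        assert r.chi2 == pytest.approx(expect)
        assert dict(r.terms_used) == {"pM3t": 0.2, "pM3m": 0.4}

    def test_tie_broken_by_family_order(self):
        terms = _terms(_full(0.2), _full(0.2))
        r1 = combine_method3(terms)
        r2 = combine_method3(terms)
        # mutation family wins the tie in both cohorts -> interaction terms
        assert dict(r1.terms_used) == {"pM3t": 0.2, "pM3m": 0.2}
        assert r1 == r2

    def test_empty_cohort_drops_to_df_two(self):
        terms = _terms({"pE1": 0.05}, None)
        r = combine_method3(terms)
        assert r.df == 2

    def test_cox_only_family_option(self):
        terms = _terms({"pQ1": 0.001, "pE1": 0.3}, {"pQ2": 0.002, "pM1": 0.4})
        r = combine_method3(terms, DoubletConfig(method3_families="cox_only"))
        assert dict(r.terms_used) == {"pE1t": 0.3, "pM1m": 0.4}


class TestScoreDoublet:
    def test_symmetry_in_drug_order(self, bundles, library):
        bt, bm = bundles
        d1, d2 = library.drugs[0], library.drugs[3]
        s12 = score_doublet((d1, d2), bt, bm, library)
        s21 = score_doublet((d2, d1), bt, bm, library)
        assert s12.method1.p_combined == s21.method1.p_combined
        assert s12.method2.p_combined == s21.method2.p_combined
        assert s12.method3.p_combined == s21.method3.p_combined

    def test_method2_terms_subset_of_method1(self, bundles, library):
        bt, bm = bundles
        s = score_doublet(tuple(library.drugs[:2]), bt, bm, library)
        assert set(l for l, _ in s.method2.terms_used) <= \
            set(l for l, _ in s.method1.terms_used)
        assert s.method1.df <= 32 and s.method2.df <= 8 and s.method3.df <= 4

    def test_ranked_table_deterministic(self, bundles, library):
        bt, bm = bundles
        pairs = enumerate_doublets(library.drugs[:2], library.drugs).pairs[:6]
        t1 = doublet_table(run_subgroup(pairs, bt, bm, library))
        t2 = doublet_table(run_subgroup(pairs, bt, bm, library))
        pd.testing.assert_frame_equal(t1, t2)


class TestSubgroups:
    def test_filter_counts_match_genotype(self, bundles):
        bt, _ = bundles
        sub = filter_subgroup(bt, "NRAS")
        assert sub.n_patients == int(
            (bt.clinical.genotype_group == "NRAS").sum())
        assert set(sub.clinical.genotype_group) == {"NRAS"}

    def test_all_is_union_of_subgroups_plus_other(self, bundles):
        bt, _ = bundles
        counted = sum(filter_subgroup(bt, g).n_patients
                      for g in ("BRAF", "NRAS", "TripleWT"))
        other = int((bt.clinical.genotype_group == "other").sum())
        assert counted + other == bt.n_patients

    def test_exact_subgroup_size_34(self):
        # clinical fixture with exactly 34 NRAS patients of 135
        geno = ["NRAS"] * 34 + ["BRAF"] * 59 + ["TripleWT"] * 28 + ["other"] * 14
        bundle = make_bundle(n=135, seed=6)
        clin = bundle.clinical.copy()
        clin["genotype_group"] = geno
        bundle = make_bundle(n=135, seed=6, clinical=clin)
        assert filter_subgroup(bundle, "NRAS").n_patients == 34

    def test_tiny_subgroup_terms_all_missing(self, library):
        bundle = make_bundle(n=30, seed=12)
        clin = bundle.clinical.copy()
        clin["genotype_group"] = ["NRAS"] * 5 + ["BRAF"] * 25
        small = make_bundle(n=30, seed=12, clinical=clin)
        lib = make_library({"d1": ["A"], "d2": ["B"]})
        scores = run_subgroup([("d1", "d2")], small, small, lib, "NRAS")
        s = scores[0]
        assert all(v is None for c in ("t", "m")
                   for v in s.terms[c].values())
        assert not s.method1.available

    def test_stratum_specific_effect_sharpens_subgroup_p(self):
        """A pair whose expression effect exists only in NRAS patients
        should look better under Method 2 in the NRAS subgroup than
        overall (most seeds)."""
        wins = 0
        n_rep = 12
        for seed in range(n_rep):
            cfg = SimulationConfig(
                seed=3000 + seed, n_patients={"t": 360, "m": 200},
                n_genes=40, drug_library_spec={"dsigdb": 2}, named_drugs={},
                genotype_fractions={
                    "t": {"BRAF": 0.3, "NRAS": 0.5, "TripleWT": 0.2},
                    "m": {"BRAF": 0.3, "NRAS": 0.5, "TripleWT": 0.2}},
            )
            bt, bm, lib, truth = simulate_cohorts(cfg)
            pair = ("dsigdb_drug_0000", "dsigdb_drug_0001")
            # survival depends on both drugs' latent factors in NRAS only
            for c, b in (("t", bt), ("m", bm)):
                f1 = truth["module_factors"][c][truth["drug_module"][pair[0]]]
                f2 = truth["module_factors"][c][truth["drug_module"][pair[1]]]
                nras = (b.clinical.genotype_group == "NRAS").to_numpy()
                scale = np.exp(-1.0 * (f1 + f2) * nras)
                b.clinical["os_time"] = b.clinical["os_time"].to_numpy() * scale
            s_all = score_doublet(pair, bt, bm, lib, "All")
            s_nras = run_subgroup([pair], bt, bm, lib, "NRAS")[0]
            if (s_nras.method2.available and s_all.method2.available
                    and s_nras.method2.p_combined < s_all.method2.p_combined):
                wins += 1
        assert wins / n_rep >= 0.7
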