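"""Inferential machinery: permutation tests, BH, enrichment, partial
correlations, clinical statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fconn.stats import (
    chi2_from_counts,
    compare_bin_profiles,
    demographics_tests,
    dice_coefficient,
    fdr_bh,
    hub_bin_profile,
    module_enrichment,
    nodal_comparison,
    partial_correlation,
    payne_corrected_calcium,
    permutation_test,
    t_from_summaries,
)


class TestPermutationTest:
    def test_identical_values_give_p_one(self, rng):
        res = permutation_test([3.0] * 5, [3.0] * 6, rng, n_perm=500)
        assert res.observed_diff == 0.0
        assert res.p_one_tailed == 1.0

    def test_extreme_separation_matches_enumeration(self, rng):
        # groups {10,10} vs {0,0}: of the 6 equal-size relabelings exactly
        # one reproduces a difference >= 10, so P(null >= obs) = 1/6
        res = permutation_test([10.0, 10.0], [0.0, 0.0], rng, n_perm=6000)
        # exhaustive enumeration oracle
        from itertools import combinations
        vals = np.array([10.0, 10.0, 0.0, 0.0])
        diffs = [vals[list(c)].mean() - np.delete(vals, list(c)).mean()
                 for c in combinations(range(4), 2)]
        exact_tail = np.mean([d >= res.observed_diff for d in diffs])
        assert exact_tail == pytest.approx(1 / 6)
        assert res.p_one_tailed == pytest.approx(exact_tail, abs=0.02)

    def test_add_one_convention_never_zero(self, rng):
        res = permutation_test([100.0, 101.0, 102.0], [0.0, 0.1, 0.2],
                               rng, n_perm=200)
        assert res.p_one_tailed >= 1 / 201

    def test_less_tail_mirrors_greater(self, rng):
        a, b = [1.0, 2.0, 1.5], [5.0, 6.0, 5.5]
        res = permutation_test(a, b, np.random.default_rng(0), tail="less",
                               n_perm=2000)
        assert res.p_one_tailed < 0.2
        assert res.observed_diff < 0

    def test_covariate_adjustment_removes_confound(self):
        # group difference entirely driven by a covariate
        rng = np.random.default_rng(5)
        z = np.concatenate([np.ones(20), np.zeros(20)])
        y = 3.0 * z + 0.1 * rng.standard_normal(40)
        res_raw = permutation_test(y[:20], y[20:], np.random.default_rng(1),
                                   n_perm=2000)
        res_adj = permutation_test(y[:20], y[20:], np.random.default_rng(1),
                                   n_perm=2000, covariates=z[:, None])
        assert res_raw.p_one_tailed < 0.01
        assert res_adj.p_one_tailed > 0.2

    def test_type_one_error_calibrated(self):
        # exchangeable groups at the study's sample sizes
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.standard_normal(51)
            res = permutation_test(x[:22], x[22:], rng, n_perm=500)
            rejections += res.p_one_tailed <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.08


class TestFdrBH:
    def test_all_tiny_rejected_all_large_kept(self):
        assert fdr_bh([0.001] * 100).all()
        assert not fdr_bh([0.9] * 50).any()

    def test_hand_worked_step_up(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        # step-up by hand: sorted p_i <= (i/10)*0.05 holds up to i=2 only
        mask = fdr_bh(p, q=0.05)
        assert mask.tolist() == [True, True] + [False] * 8

    def test_empty_input(self):
        assert fdr_bh([]).size == 0


class TestNodalComparison:
    def test_identical_groups_flag_nothing(self, rng):
        x = rng.standard_normal((10, 30))
        flagged, table = nodal_comparison(x[:5], x[5:], rng, n_perm=300)
        assert flagged.size == 0

    def test_planted_decrease_detected_and_reorder_invariant(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((24, 40)) * 0.3 + 5.0
        a = base[:10].copy()
        b = base[10:]
        a[:, :8] -= 2.0  # strong decrease in first 8 nodes
        flagged, _ = nodal_comparison(a, b, np.random.default_rng(0), n_perm=2000)
        assert set(flagged) == set(range(8))
        perm = np.random.default_rng(1).permutation(40)
        flagged_p, _ = nodal_comparison(a[:, perm], b[:, perm],
                                        np.random.default_rng(0), n_perm=2000)
        assert set(perm[flagged_p]) == set(flagged)


class TestHubBins:
    def test_uniform_grid_fills_bins_equally(self):
        vals = np.repeat(np.arange(8, dtype=float), 16)
        prof = hub_bin_profile(vals)
        assert np.allclose(prof.percentages, 12.5)

    def test_constant_input_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            prof = hub_bin_profile(np.full(64, 3.0))
        assert prof.percentages[0] == 100.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(9, 300))
    def test_percentages_sum_to_hundred(self, seed, n):
        vals = np.random.default_rng(seed).standard_normal(n)
        prof = hub_bin_profile(vals)
        assert prof.percentages.sum() == pytest.approx(100.0, abs=1e-9)
        assert (prof.percentages >= 0).all() and prof.percentages.size == 8

    def test_group_comparison_runs(self, rng):
        pa = [hub_bin_profile(rng.standard_normal(64)) for _ in range(5)]
        pb = [hub_bin_profile(rng.standard_normal(64)) for _ in range(5)]
        table = compare_bin_profiles(pa, pb, rng, n_perm=200)
        assert len(table) == 8
        assert ((table["p_one_tailed"] > 0) & (table["p_one_tailed"] <= 1)).all()


class TestModuleEnrichment:
    def test_all_nodes_flagged_p_one(self, rng):
        labels = np.repeat([0, 1], 10)
        res = module_enrichment(np.arange(20), labels, rng, n_draws=200)
        assert np.allclose(res.p_empirical, 1.0)

    def test_agrees_with_hypergeometric_tail(self, rng):
        n, m_sizes = 60, np.array([25, 20, 15])
        labels = np.repeat(np.arange(3), m_sizes)
        flagged = np.concatenate([np.arange(15), np.arange(25, 30)])  # 15/5/0
        n_draws = 4000
        res = module_enrichment(flagged, labels, rng, n_draws=n_draws)
        for s in range(3):
            obs = res.observed[s]
            tail = sps.hypergeom.sf(obs - 1, n, m_sizes[s], flagged.size)
            se = np.sqrt(tail * (1 - tail) / n_draws)
            assert abs(res.p_empirical[s] - tail) <= 3 * se + 1 / n_draws


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x = rng.standard_normal(40)
        y = x + rng.standard_normal(40)
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_controlling_shared_variable_kills_correlation(self, rng):
        z = rng.standard_normal(60)
        r, _ = partial_correlation(z + 0 * z, z.copy(), covariates=z[:, None])
        assert abs(r) < 1e-8

    def test_matches_recursive_formula(self, rng):
        z = rng.standard_normal(200)
        x = rng.standard_normal(200)
        y = 2 * x + 3 * z + 0.5 * rng.standard_normal(200)
        r, _ = partial_correlation(x, y, covariates=z[:, None])
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(expected, abs=1e-10)

    def test_complete_cases_only(self, rng):
        x = rng.standard_normal(30)
        y = x + 0.1 * rng.standard_normal(30)
        y[3] = np.nan
        r_full, _ = partial_correlation(np.delete(x, 3), np.delete(y, 3))
        r_nan, _ = partial_correlation(x, y)
        assert r_nan == pytest.approx(r_full, abs=1e-12)


class TestClinicalStats:
    @pytest.mark.parametrize("ca,alb,expected", [
        (2.20, 40.0, 2.20),
        (2.20, 30.0, 2.40),
        (2.20, 50.0, 2.00),
    ])
    def test_payne_formula(self, ca, alb, expected):
        assert payne_corrected_calcium(ca, alb) == pytest.approx(expected)

    def test_gender_chi_square_matches_printed_value(self):
        _, p = chi2_from_counts((16, 6), (19, 10))
        assert p == pytest.approx(0.583, abs=0.001)

    def test_age_t_test_matches_printed_value(self):
        _, p = t_from_summaries(38.0, 10.5, 22, 42.1, 8.4, 29)
        assert p == pytest.approx(0.127, abs=0.001)

    def test_identical_groups_chi_square_zero(self):
        import pandas as pd
        manifest = pd.DataFrame({
            "group": ["a"] * 10 + ["b"] * 10,
            "sex": [1, 0] * 10,
            "age": list(range(10)) * 2,
        })
        out = demographics_tests(manifest)
        assert out.loc["sex", "statistic"] == pytest.approx(0.0)
        assert out.loc["sex", "p_value"] == pytest.approx(1.0)
        assert out.loc["age", "p_value"] == pytest.approx(1.0)


class TestDice:
    @pytest.mark.parametrize("a,b,expected", [
        ({1, 2, 3}, {1, 2, 3}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2}, {2, 3}, 0.5),
    ])
    def test_known_overlaps(self, a, b, expected):
        assert dice_coefficient(a, b) == pytest.approx(expected)

    def test_both_empty_defined_as_one(self):
        with pytest.warns(UserWarning):
            assert dice_coefficient(set(), set()) == 1.0
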