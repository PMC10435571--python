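import numpy as np
import pytest
from scipy import stats

from bgregulome import (
    HaplotypeFrequencies,
    anova_bonferroni,
    compute_ld,
    delta_delta_ct,
    estimate_haplotypes,
    genotype_concordance,
    geometric_mfi,
    luciferase_ratio_test,
    ols_dose_regression,
)
from bgregulome.cohort import (
    CollinearityError,
    LDUndefinedError,
    genotype_loglikelihood,
)


def _hf(p_AB, p_Ab, p_aB, p_ab):
    return HaplotypeFrequencies(p_AB, p_Ab, p_aB, p_ab)


def _draw_doses(rng, freqs, n):
    haps = rng.choice(4, size=(n, 2), p=freqs)
    dose1 = np.isin(haps, (2, 3)).sum(axis=1)
    dose2 = np.isin(haps, (1, 3)).sum(axis=1)
    return np.column_stack([dose1, dose2])


class TestHaplotypeEstimation:
    def test_no_double_hets_reduces_to_direct_counting(self):
        table = [(0, 0), (0, 0), (2, 2), (1, 0), (0, 1), (2, 1)]
        rule = estimate_haplotypes(table, mode="counting-rule")
        em = estimate_haplotypes(table, mode="em")
        assert rule.estimation_mode == em.estimation_mode == "direct"
        # hand gamete count: AB x2, AB x2, ab x2, aB+AB, AB+Ab, ab+aB
        expected = np.array([6, 1, 2, 3]) / 12
        np.testing.assert_allclose(rule.frequencies, expected)
        np.testing.assert_allclose(em.frequencies, expected)

    def test_complete_ld_cohort_has_two_haplotypes_only(self):
        # every sample has dose1 == dose2, as in a perfectly linked cohort
        table = [(0, 0)] * 70 + [(1, 1)] * 25 + [(2, 2)] * 5
        hf = estimate_haplotypes(table, mode="counting-rule")
        assert hf.p_Ab == 0.0 and hf.p_aB == 0.0
        assert hf.p_AB > 0 and hf.p_ab > 0
        assert hf.n_double_het == 25

    def test_double_hets_follow_the_common_configuration(self):
        # unambiguous samples make AB/ab overwhelmingly the common pair
        table = [(0, 0)] * 40 + [(2, 2)] * 10 + [(1, 1)] * 10
        hf = estimate_haplotypes(table, mode="counting-rule")
        assert hf.p_Ab == 0.0 and hf.p_aB == 0.0
        assert hf.p_ab == pytest.approx((2 * 10 + 10) / 120)

    def test_em_recovers_known_frequencies(self):
        truth = np.array([0.80, 0.04, 0.01, 0.15])
        rng = np.random.default_rng(42)
        estimates = np.array(
            [
                estimate_haplotypes(_draw_doses(rng, truth, 400), mode="em").frequencies
                for _ in range(200)
            ]
        )
        assert np.abs(estimates.mean(axis=0) - truth).max() < 0.02

    def test_em_likelihood_never_below_counting_rule(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            freqs = rng.dirichlet([2, 1, 1, 2])
            table = _draw_doses(rng, freqs, 120)
            ll_rule = genotype_loglikelihood(
                estimate_haplotypes(table, mode="counting-rule"), table
            )
            ll_em = genotype_loglikelihood(
                estimate_haplotypes(table, mode="em"), table
            )
            assert ll_em >= ll_rule - 1e-9

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            estimate_haplotypes([], mode="em")


class TestComputeLd:
    def test_absent_haplotype_with_nonzero_d_gives_dprime_one(self):
        ld = compute_ld(_hf(0.55, 0.25, 0.20, 0.00))
        assert ld.D != 0
        assert ld.D_prime == 1.0

    def test_independence_gives_zero(self):
        ld = compute_ld(_hf(0.64, 0.16, 0.16, 0.04))
        assert ld.D == pytest.approx(0.0, abs=1e-15)
        assert ld.D_prime == 0.0
        assert ld.r_squared == 0.0

    def test_hand_evaluated_closed_form(self):
        # p_A=0.8, p_B=0.8 -> D = 0.7 - 0.64 = 0.06
        # D_max = min(0.8*0.2, 0.2*0.8) = 0.16 -> D' = 0.375
        # r^2 = 0.06^2 / (0.8*0.2*0.8*0.2) = 0.140625
        ld = compute_ld(_hf(0.7, 0.1, 0.1, 0.1))
        assert ld.D == pytest.approx(0.06)
        assert ld.D_max == pytest.approx(0.16)
        assert ld.D_prime == pytest.approx(0.375)
        assert ld.r_squared == pytest.approx(0.140625)

    def test_monomorphic_locus_is_signalled(self):
        with pytest.raises(LDUndefinedError):
            compute_ld(_hf(0.8, 0.0, 0.2, 0.0))

    def test_r_squared_bounded_by_dprime_squared(self, rng):
        for _ in range(200):
            f = rng.dirichlet([1, 1, 1, 1])
            try:
                ld = compute_ld(_hf(*f))
            except LDUndefinedError:
                continue
            assert ld.r_squared <= ld.D_prime**2 + 1e-12

    def test_invariant_to_joint_allele_relabeling(self, rng):
        for _ in range(50):
            p_AB, p_Ab, p_aB, p_ab = rng.dirichlet([1, 1, 1, 1])
            try:
                a = compute_ld(_hf(p_AB, p_Ab, p_aB, p_ab))
                b = compute_ld(_hf(p_ab, p_aB, p_Ab, p_AB))  # A<->a and B<->b
            except LDUndefinedError:
                continue
            assert abs(a.D) == pytest.approx(abs(b.D))
            assert a.D_prime == pytest.approx(b.D_prime)
            assert a.r_squared == pytest.approx(b.r_squared)


class TestConcordance:
    def test_perfectly_linked_table_has_no_separable_samples(self):
        rep = genotype_concordance([(0, 0), (1, 1), (2, 2)])
        assert rep.n_separable == 0

    def test_single_discordant_sample(self):
        rep = genotype_concordance([(0, 0)] * 9 + [(0, 1)])
        assert rep.n_separable == 1
        assert rep.fraction == pytest.approx(0.1)

    def test_separable_fraction_matches_analytic_expectation(self):
        freqs = np.array([0.833, 0.010, 0.004, 0.153])
        # P(dose1 == dose2) from the 10 unordered genotype pairs
        p_equal = 0.0
        for h1 in range(4):
            for h2 in range(4):
                d1 = (h1 in (2, 3)) + (h2 in (2, 3))
                d2 = (h1 in (1, 3)) + (h2 in (1, 3))
                if d1 == d2:
                    p_equal += freqs[h1] * freqs[h2]
        expected = 1 - p_equal
        rng = np.random.default_rng(3)
        fracs = [
            genotype_concordance(_draw_doses(rng, freqs, 396)).fraction
            for _ in range(200)
        ]
        se = np.sqrt(expected * (1 - expected) / 396 / 200)
        assert np.mean(fracs) == pytest.approx(expected, abs=5 * se)


class TestGeometricMfi:
    def test_constant_list(self):
        assert geometric_mfi([7.5, 7.5, 7.5]) == pytest.approx(7.5)

    def test_two_point_geometric_mean(self):
        assert geometric_mfi([1.0, 100.0]) == pytest.approx(10.0)

    def test_equals_log_domain_oracle(self, rng):
        values = rng.lognormal(3.0, 0.5, size=500)
        assert geometric_mfi(values) == pytest.approx(
            np.exp(np.log(values).mean()), abs=1e-12
        )

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            geometric_mfi([1.0, 0.0])


class TestAnova:
    def test_identical_constant_groups(self):
        res = anova_bonferroni({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0
        assert all(adj == 1.0 for _, adj in res.pairwise.values())

    def test_two_groups_reduce_to_pooled_t(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = anova_bonferroni({"x": x, "y": y})
        t, p = stats.ttest_ind(x, y, equal_var=True)
        assert res.f_statistic == pytest.approx(t**2)
        assert res.p_value == pytest.approx(p)
        # single pair: Bonferroni m = 1
        assert res.pairwise[("x", "y")][1] == pytest.approx(p)

    def test_dose_groups_with_large_effect_all_significant(self, rng):
        groups = {
            0: rng.normal(1000, 100, 30),
            1: rng.normal(600, 100, 30),
            2: rng.normal(300, 100, 30),
        }
        res = anova_bonferroni(groups)
        assert res.p_value < 1e-3
        assert all(adj < 0.05 for _, adj in res.pairwise.values())

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_bonferroni({"a": [1.0], "b": [2.0, 3.0]})


class TestOls:
    def test_exact_fit_recovers_coefficients(self):
        doses = [(0, 0), (1, 1), (2, 0), (0, 1), (1, 0), (2, 1)]
        y = [5 - 2 * d1 for d1, _ in doses]
        res = ols_dose_regression(y, doses)
        assert res.terms["dose_locus1"].beta == pytest.approx(-2.0, abs=1e-10)
        assert res.terms["dose_locus2"].beta == pytest.approx(0.0, abs=1e-10)
        assert res.terms["intercept"].beta == pytest.approx(5.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 60
        doses = np.column_stack(
            [rng.integers(0, 3, n), rng.integers(0, 3, n)]
        )
        y = rng.normal(0, 1, n) + 0.7 * doses[:, 0]
        res = ols_dose_regression(y, doses)
        X = np.column_stack([np.ones(n), doses])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 3)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        tcrit = stats.t.ppf(0.975, n - 3)
        for i, name in enumerate(("intercept", "dose_locus1", "dose_locus2")):
            term = res.terms[name]
            se = np.sqrt(cov[i, i])
            assert term.beta == pytest.approx(beta[i], abs=1e-8)
            assert term.ci_low == pytest.approx(beta[i] - tcrit * se, abs=1e-8)
            assert term.ci_high == pytest.approx(beta[i] + tcrit * se, abs=1e-8)
            t_stat = beta[i] / se
            p = 2 * stats.t.sf(abs(t_stat), n - 3)
            assert term.p_value == pytest.approx(p, abs=1e-10)

    def test_complete_ld_doses_raise_collinearity(self):
        doses = [(0, 0), (1, 1), (2, 2), (1, 1), (0, 0)]
        with pytest.raises(CollinearityError, match="single-locus"):
            ols_dose_regression([1.0, 2.0, 3.0, 2.5, 1.5], doses)


class TestDeltaDeltaCt:
    def test_calibrator_equal_sample_gives_zero(self):
        assert delta_delta_ct([24, 24, 24], [20, 20, 20], 4.0) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # mean(target) = 25.1, mean(ref) = 20.0, dCt = 5.1, ddCt = 1.1
        val = delta_delta_ct([25.0, 25.2, 25.1], [20.0, 20.1, 19.9], 4.0)
        assert val == pytest.approx(1.1)

    def test_one_cycle_shift_is_linear(self):
        base = delta_delta_ct([25.0, 25.2, 25.1], [20.0, 20.1, 19.9], 4.0)
        down = delta_delta_ct([24.0, 24.2, 24.1], [20.0, 20.1, 19.9], 4.0)
        assert down == pytest.approx(base - 1.0)

    def test_missing_replicate_rejected(self):
        with pytest.raises(ValueError):
            delta_delta_ct([25.0, 25.2], [20.0, 20.1, 19.9], 4.0)
        with pytest.raises(ValueError):
            delta_delta_ct([25.0, 25.2, np.nan], [20.0, 20.1, 19.9], 4.0)


class TestLuciferase:
    def test_identical_construct_is_degenerate(self):
        wells = [[2.0, 2.0, 2.0], [3.0, 3.0, 3.0], [2.5, 2.5, 2.5]]
        renilla = [[1.0, 1.0, 1.0]] * 3
        res = luciferase_ratio_test(
            {"empty": wells, "enh": wells}, {"empty": renilla, "enh": renilla},
            baseline="empty",
        )
        cmp = res.comparisons["enh"]
        assert cmp.degenerate
        assert cmp.p_value == 1.0
        assert cmp.relative_activity == pytest.approx(1.0)

    def test_matches_hand_computed_paired_t(self):
        # experiment means 2.0/2.2/1.9 vs 1.0/1.1/0.9
        firefly = {
            "enh": [[2.0], [2.2], [1.9]],
            "empty": [[1.0], [1.1], [0.9]],
        }
        renilla = {"enh": [[1.0]] * 3, "empty": [[1.0]] * 3}
        res = luciferase_ratio_test(firefly, renilla, baseline="empty")
        d = np.array([1.0, 1.1, 1.0])
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p_hand = 2 * stats.t.sf(abs(t_hand), 2)
        cmp = res.comparisons["enh"]
        assert cmp.t_statistic == pytest.approx(t_hand)
        assert cmp.p_value == pytest.approx(p_hand)
        assert cmp.relative_activity == pytest.approx(2.0333333, abs=1e-6)

    def test_nonpositive_renilla_rejected(self):
        with pytest.raises(ValueError):
            luciferase_ratio_test(
                {"a": [[1.0]], "b": [[1.0]]},
                {"a": [[0.0]], "b": [[1.0]]},
                baseline="b",
            )
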