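"""First-principles statistics: t, Mann–Whitney U, χ²."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

import msbdyn.stats as mstats
from msbdyn.errors import (ConfigError, DegenerateVarianceError,
                           InsufficientDataError)


def t_density(x, df):
    """Student t density written out from the gamma function."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


class TestTTest:
    def test_identical_samples_give_half(self):
        r = mstats.t_test_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                     alternative="greater")
        assert r.statistic == 0.0 and r.p_value == 0.5

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(DegenerateVarianceError):
            mstats.t_test_one_tailed([0.0] * 4, [1.0] * 4, alternative="less")

    def test_direction_must_be_explicit(self):
        with pytest.raises(ConfigError):
            mstats.t_test_one_tailed([1.0, 2.0], [3.0, 4.0],
                                     alternative="two-sided")

    def test_p_matches_density_quadrature(self, rng):
        """One-tailed p equals the integral of the t density past the statistic."""
        for _ in range(25):
            a = rng.normal(0, 1, size=rng.integers(3, 12))
            b = rng.normal(0.5, 1.2, size=rng.integers(3, 12))
            r = mstats.t_test_one_tailed(a, b, alternative="greater")
            expected, _ = integrate.quad(t_density, r.statistic, np.inf,
                                         args=(r.df,))
            assert r.p_value == pytest.approx(expected, abs=1e-8)

    def test_matches_scipy_reference(self, rng):
        a = rng.normal(0, 1, size=10)
        b = rng.normal(1, 1, size=12)
        r = mstats.t_test_one_tailed(a, b, alternative="less")
        ref = sps.ttest_ind(a, b, alternative="less")
        assert r.p_value == pytest.approx(ref.pvalue)
        r_w = mstats.t_test_one_tailed(a, b, alternative="less",
                                       equal_var=False)
        ref_w = sps.ttest_ind(a, b, alternative="less", equal_var=False)
        assert r_w.p_value == pytest.approx(ref_w.pvalue)

    def test_insufficient_data_raises(self):
        with pytest.raises(InsufficientDataError):
            mstats.t_test_one_tailed([1.0], [1.0, 2.0], alternative="greater")

    def test_type_one_error_calibrated_under_null(self):
        """Empirical size at α=0.05 within 3 binomial SE over 2000 replicates."""
        rng = np.random.default_rng(99)
        reps = 2000
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, 1, size=18)
            b = rng.normal(0, 1, size=18)
            if mstats.t_test_one_tailed(a, b, alternative="greater").significant:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)


def enumeration_oracle_p(a, b):
    """Exact two-tailed Mann–Whitney p by direct enumeration (independent)."""
    pooled = np.concatenate([a, b])
    m = len(a)
    center = m * len(b) / 2

    def u_of(group_a, group_b):
        gt = sum(1 for x in group_a for y in group_b if x > y)
        eq = sum(1 for x in group_a for y in group_b if x == y)
        return gt + 0.5 * eq
    observed = abs(u_of(a, b) - center)
    total = extreme = 0
    for chosen in combinations(range(len(pooled)), m):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(chosen)] = True
        total += 1
        if abs(u_of(pooled[mask], pooled[~mask]) - center) >= observed - 1e-9:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_complete_separation_three_vs_three(self):
        r = mstats.mann_whitney_two_tailed([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 20)  # 2 of C(6,3) assignments
        assert "exact" in r.method

    def test_equal_singletons_give_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            r = mstats.mann_whitney_two_tailed([3.0], [3.0])
        assert r.p_value == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            a = rng.normal(0, 1, size=rng.integers(2, 7))
            b = rng.normal(0.5, 1, size=rng.integers(2, 7))
            r = mstats.mann_whitney_two_tailed(a, b)
            assert r.p_value == pytest.approx(enumeration_oracle_p(a, b))

    def test_exact_with_ties_matches_enumeration(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, size=5).astype(float)
            b = rng.integers(0, 4, size=5).astype(float)
            if np.unique(np.concatenate([a, b])).size == 1:
                continue
            r = mstats.mann_whitney_two_tailed(a, b)
            assert r.p_value == pytest.approx(enumeration_oracle_p(a, b))

    def test_separation_exact_vs_approximation_order_of_magnitude(self):
        """Complete separation at n=8+8: both paths land in the same decade."""
        a = list(range(8))
        b = [x + 7.5 for x in range(8)]
        exact = mstats.mann_whitney_two_tailed(a, b)
        approx = mstats.mann_whitney_two_tailed(a, b, exact_max_n=0,
                                                exact_max_product=0)
        assert "exact" in exact.method and "approximation" in approx.method
        assert abs(math.log10(exact.p_value) - math.log10(approx.p_value)) < 1

    def test_approximation_matches_scipy(self, rng):
        a = rng.normal(0, 1, size=25)
        b = rng.normal(0.4, 1, size=30)
        r = mstats.mann_whitney_two_tailed(a, b, exact_max_n=0,
                                           exact_max_product=0)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_type_one_error_calibrated_exact_path(self):
        rng = np.random.default_rng(7)
        reps = 2000
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, 1, size=8)
            b = rng.normal(0, 1, size=8)
            r = mstats.mann_whitney_two_tailed(a, b)
            assert "exact" in r.method
            if r.significant:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)


class TestChiSquareGof:
    def test_orientation_distribution_example(self):
        """Observed 14:5:3 against 7:9:6 expected proportions → p ≈ 0.006."""
        r = mstats.chi_square_gof([14, 5, 3], [7, 9, 6])
        assert r.df == 2
        assert r.statistic == pytest.approx(10.2778, abs=1e-3)
        assert r.p_value == pytest.approx(0.006, abs=5e-4)

    def test_observed_equals_expected(self):
        r = mstats.chi_square_gof([10, 20, 30], [10, 20, 30])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_matches_hand_summation(self, rng):
        for _ in range(50):
            obs = rng.integers(1, 40, size=rng.integers(2, 6))
            exp = rng.uniform(0.5, 5, size=obs.size)
            exp_scaled = exp * obs.sum() / exp.sum()
            hand = sum((o - e) ** 2 / e for o, e in zip(obs, exp_scaled))
            r = mstats.chi_square_gof(obs, exp)
            assert r.statistic == pytest.approx(hand)
            ref = sps.chisquare(obs, exp_scaled)
            assert r.p_value == pytest.approx(ref.pvalue)

    def test_zero_expected_cell_raises(self):
        with pytest.raises(ConfigError):
            mstats.chi_square_gof([1, 2], [0, 1])

    def test_p_monotone_decreasing_in_statistic(self):
        ps = [mstats.chi_square_gof([10 + k, 10 - k], [1, 1]).p_value
              for k in range(0, 9, 2)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestChiSquareContingency:
    def test_orientation_counts_as_contingency_table(self):
        r = mstats.chi_square_contingency([[14, 5, 3], [7, 9, 6]])
        assert r.df == 2
        assert r.statistic == pytest.approx(4.48, abs=0.01)

    def test_independent_table(self):
        r = mstats.chi_square_contingency([[1, 1], [1, 1]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_2x2_closed_form(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(1, 30, size=4)
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / \
                ((a + b) * (c + d) * (a + c) * (b + d))
            r = mstats.chi_square_contingency([[a, b], [c, d]])
            assert r.statistic == pytest.approx(closed)

    def test_matches_scipy_reference(self, rng):
        table = rng.integers(1, 30, size=(3, 4))
        r = mstats.chi_square_contingency(table)
        chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
        assert r.statistic == pytest.approx(chi2)
        assert r.p_value == pytest.approx(p)
        assert r.df == df

    def test_zero_marginal_raises(self):
        with pytest.raises(ConfigError):
            mstats.chi_square_contingency([[0, 0], [1, 2]])
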