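import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from fhresponse.errors import (
    DegeneratePredictorError,
    DegenerateTableError,
    EmptyInputError,
)
from fhresponse.stats import (
    contingency_test,
    group_summary,
    linear_regression,
    mann_whitney,
    quantile_type6,
)


class TestQuantileType6:
    def test_published_quartile_anchors(self):
        """The (n+1)p rule is pinned by the published six-patient IQRs."""
        reductions = [11.8, 19.8, 21.4, 22.5, 76.1, 76.6]
        assert quantile_type6(reductions, 0.25) == pytest.approx(17.8, abs=0.05)
        post = [33, 70, 99, 107, 149, 329]
        assert quantile_type6(post, 0.75) == pytest.approx(194)

    def test_single_element_clamped(self):
        for p in (0.1, 0.5, 0.9):
            assert quantile_type6([5], p) == 5

    def test_errors(self):
        with pytest.raises(EmptyInputError):
            quantile_type6([], 0.5)
        with pytest.raises(ValueError):
            quantile_type6([1, 2], 0.0)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_median_equals_order_statistic_rule(self, values):
        """Median is the middle value (odd n) or mean of the two central (even n)."""
        s = sorted(values)
        n = len(s)
        expected = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert quantile_type6(values, 0.5) == pytest.approx(expected, abs=1e-9)


class TestGroupSummary:
    def test_six_patient_baseline_summary(self):
        s = group_summary([169, 126, 138, 138, 410, 299])
        assert round(s.median) == 154  # 153.5 rounds to the printed integer
        assert (s.q1, s.q3) == (135, 326.75)
        assert s.n == 6

    def test_constant_and_odd_lists(self):
        s = group_summary([7, 7, 7])
        assert s.median == s.q1 == s.q3 == 7
        assert group_summary([1, 2, 3]).median == 2

    def test_ordering_invariant(self):
        s = group_summary([5, 1, 9, 3, 7])
        assert s.q1 <= s.median <= s.q3


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples_symmetric(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.z_value == 0
        assert res.p_two_sided == 1

    @given(
        a=st.lists(st.integers(0, 1000), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 1000), min_size=1, max_size=8),
    )
    def test_rank_sum_identity(self, a, b):
        """U_a + U_b = n1*n2 (with mid-rank ties U is the tie-adjusted count)."""
        ua = mann_whitney(a, b).u_statistic
        ub = mann_whitney(b, a).u_statistic
        assert ua + ub == pytest.approx(len(a) * len(b))

    @pytest.mark.parametrize("seed", [11, 23, 37])
    @pytest.mark.parametrize("n1, n2", [(3, 3), (4, 5), (6, 6)])
    def test_exact_p_matches_brute_force_enumeration(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(100)[: n1 + n2].astype(float)  # distinct, no ties
        a, b = vals[:n1], vals[n1:]
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(oracles.mwu_exact_p_two_sided(a, b))

    def test_asymptotic_close_to_exact_at_n10(self):
        """Normal approximation tracks the exact p closely for n1=n2=10.

        Without continuity correction (the convention used here) the
        worst-case gap over all U values at these sample sizes is 0.0341,
        so 0.035 is the tight bound; most draws sit well under 0.02.
        """
        rng = np.random.default_rng(42)
        from scipy.stats import mannwhitneyu

        gaps = []
        for _ in range(20):
            vals = rng.permutation(10_000)[:20].astype(float)
            a, b = vals[:10], vals[10:]
            asym = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                use_continuity=False).pvalue
            exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            gaps.append(abs(asym - exact))
        assert max(gaps) < 0.035

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyInputError):
            mann_whitney([], [1, 2])


class TestLinearRegression:
    def test_perfect_fit(self):
        fit = linear_regression([1, 2, 3, 4], [2, 4, 6, 8])
        assert fit.slope == pytest.approx(2)
        assert fit.r_squared == pytest.approx(1)

    def test_constant_response(self):
        fit = linear_regression([1, 2, 3], [5, 5, 5])
        assert fit.slope == 0
        assert fit.r_squared == 0
        assert fit.p_slope == 1

    def test_hand_ols_four_points(self):
        # Sxy = 3, Sxx = 5, Syy = 5 -> slope 0.6, R^2 = 3^2/(5*5) = 0.36
        fit = linear_regression([1, 2, 3, 4], [2, 1, 4, 3])
        assert fit.slope == pytest.approx(0.6)
        assert fit.r_squared == pytest.approx(0.36)

    @pytest.mark.parametrize("seed", [3, 17])
    def test_matches_closed_form_sums(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = 1.5 * x + rng.normal(size=10)
        fit = linear_regression(x, y)
        slope, intercept, r2, p = oracles.ols_closed_form(x, y)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r_squared == pytest.approx(r2)
        assert fit.p_slope == pytest.approx(p)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            linear_regression([1, 1, 1], [1, 2, 3])


class TestContingency:
    def test_independence_gives_unit_p(self):
        res = contingency_test([[10, 10], [10, 10]])
        assert res.statistic == 0
        assert res.p_value == 1
        assert res.method_used == "chi_square"

    def test_sparse_2x2_falls_back_to_fisher(self):
        res = contingency_test([[5, 0], [0, 5]])
        assert res.method_used == "fisher_exact"
        assert res.p_value == pytest.approx(2 / 252)  # 0.00794
        assert res.p_value == pytest.approx(
            oracles.fisher_exact_p_two_sided([[5, 0], [0, 5]])
        )

    def test_2x3_chi_square_matches_direct_formula(self):
        table = [[20, 30, 25], [15, 25, 40]]
        res = contingency_test(table)
        assert res.method_used == "chi_square"
        assert res.dof == 2
        assert res.statistic == pytest.approx(oracles.chi_square_direct(table))

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            contingency_test([[0, 0], [3, 4]])
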