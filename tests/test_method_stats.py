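import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ttcquant.exceptions import ContractError, DegenerateSampleError
from ttcquant.method_stats import (
    PairedSample,
    compare_methods,
    ks_normality,
    linear_regression,
    paired_t_test,
    pearson_r,
    variance_ratio_test,
)


def sample(x, y):
    return PairedSample.from_arrays(x, y)


class TestPairedT:
    def test_hand_computed_example(self):
        # d = (-1, -2, -3): mean -2, sd 1, t = -2 / (1/sqrt(3))
        res = paired_t_test(sample([1, 2, 3], [2, 4, 6]))
        assert res.statistic == pytest.approx(-2 * np.sqrt(3), abs=1e-9)
        assert res.statistic == pytest.approx(-3.4641, abs=1e-4)
        assert res.df == 2
        assert res.p_value == pytest.approx(float(2 * sps.t.sf(2 * np.sqrt(3), 2)), abs=1e-12)

    def test_identical_methods_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            paired_t_test(sample([1, 2, 3], [1, 2, 3]))

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            paired_t_test(sample([10, 20], [9, 19]))

    def test_df_is_ten_for_eleven_pairs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(30, 5, 11)
        res = paired_t_test(sample(x, x + rng.normal(0, 1, 11)))
        assert res.df == 10

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = paired_t_test(sample(x, y))
        b = paired_t_test(sample(y, x))
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(1.0, 6.0)
        res = pearson_r(sample(x, 2 * x + 1))
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        res = pearson_r(sample([1, 2, 3, 4], [4, 3, 2, 1]))
        assert res.statistic == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # Sxy = 10, Sxx = 10, Syy = 14.8 -> r = 10 / sqrt(148)
        res = pearson_r(sample([1, 2, 3, 4, 5], [2, 1, 4, 3, 6]))
        assert res.statistic == pytest.approx(10.0 / np.sqrt(148.0), abs=1e-12)
        assert res.df == 3

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            pearson_r(sample([1, 1, 1], [1, 2, 3]))

    def test_needs_three_points(self):
        with pytest.raises(ContractError):
            pearson_r(sample([1, 2], [3, 4]))

    @given(seed=st.integers(0, 5000),
           a=st.floats(0.5, 3), b=st.floats(-10, 10),
           c=st.floats(0.5, 3), d=st.floats(-10, 10))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_positive_affine_maps(self, seed, a, b, c, d):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=6), rng.normal(size=6)
        r0 = pearson_r(sample(x, y)).statistic
        r1 = pearson_r(sample(a * x + b, c * y + d)).statistic
        assert r1 == pytest.approx(r0, abs=1e-9)
        r2 = pearson_r(sample(-x, y)).statistic
        assert r2 == pytest.approx(-r0, abs=1e-9)


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = linear_regression(sample(x, 2 * x + 1))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        fit = linear_regression(sample([1, 2, 3], [5, 5, 5]))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_closed_form_three_points(self):
        fit = linear_regression(sample([0, 1, 2], [1, 3, 4]))
        assert fit.slope == pytest.approx(1.5, abs=1e-12)
        assert fit.intercept == pytest.approx(7.0 / 6.0, abs=1e-12)

    def test_constant_x_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            linear_regression(sample([2, 2, 2], [1, 2, 3]))

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_r_squared_equals_squared_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        fit = linear_regression(sample(x, y))
        r = pearson_r(sample(x, y)).statistic
        assert fit.r_squared == pytest.approx(r * r, abs=1e-9)


class TestKSNormality:
    def test_statistic_bounds(self):
        rng = np.random.default_rng(2)
        res = ks_normality(rng.normal(size=25))
        assert 0.0 <= res.statistic <= 1.0
        assert 0.0 <= res.p_value <= 1.0

    def test_normal_quantiles_give_small_d(self):
        n = 20
        values = sps.norm.ppf(np.arange(1, n + 1) / (n + 1))
        res = ks_normality(values)
        assert res.statistic < 0.1

    def test_uniform_sample_rejected_on_most_seeds(self):
        # 5% asymptotic critical value: D ~ 1.358 / sqrt(n).  Because mu and
        # sigma are fitted from the sample, the sup-distance of uniform data
        # to its fitted normal is only ~0.042, so a large n is needed for the
        # critical value to drop below it.
        n, rejections = 2000, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = ks_normality(rng.uniform(0, 1, n))
            if res.statistic > 1.358 / np.sqrt(n):
                rejections += 1
        assert rejections >= 12

    def test_d_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(3)
        v = rng.normal(10, 2, 40)
        res = ks_normality(v)
        mu, sd = v.mean(), v.std(ddof=1)
        grid_d = 0.0
        sv = np.sort(v)
        for i, xi in enumerate(sv):
            f = sps.norm.cdf(xi, mu, sd)
            ecdf_hi = (i + 1) / len(sv)
            ecdf_lo = i / len(sv)
            grid_d = max(grid_d, abs(ecdf_hi - f), abs(ecdf_lo - f))
        assert res.statistic == pytest.approx(grid_d, abs=1e-12)

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            ks_normality([4, 4, 4, 4])


class TestVarianceRatio:
    def test_identical_samples_give_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = variance_ratio_test(x, x)
        assert res.statistic == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        x = [0.0, 2.0, 4.0]  # variance 4
        y = [0.0, 1.0, 2.0]  # variance 1
        res = variance_ratio_test(x, y)
        assert res.statistic == pytest.approx(4.0, abs=1e-12)
        assert res.df == (2, 2)
        assert statistics.variance(x) / statistics.variance(y) == pytest.approx(4.0)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_ratio_at_least_one(self, seed):
        rng = np.random.default_rng(seed)
        res = variance_ratio_test(rng.normal(size=6), rng.normal(size=9))
        assert res.statistic >= 1.0
        assert 0.0 <= res.p_value <= 1.0

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            variance_ratio_test([1, 1, 1], [1, 2, 3])


class TestCompareMethods:
    def test_identical_methods_reported_as_note(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        report = compare_methods(sample(x, x.copy()))
        assert report.paired_t is None
        assert any("identical" in note for note in report.notes)
        assert report.pearson.statistic == pytest.approx(1.0)

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(10, 50, 11)
        y = x - 5.0 + rng.normal(0, 0.05, 11)
        report = compare_methods(sample(x, y))
        assert report.paired_t is not None
        assert report.paired_t.p_value < 0.01

    def test_df_ten_for_eleven_animals(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(10, 50, 11)
        y = x + rng.normal(0, 1.0, 11)
        report = compare_methods(sample(x, y))
        assert report.paired_t.df == 10

    def test_text_and_records(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(10, 50, 11)
        y = x + rng.normal(0, 1.0, 11)
        report = compare_methods(sample(x, y))
        text = report.to_text()
        assert "paired t-test" in text and "Pearson" in text
        quantities = {row["quantity"] for row in report.to_records()}
        assert "paired_t" in quantities and "pearson_r" in quantities


class TestAgainstReferenceImplementations:
    """Cross-checks against scipy's independent implementations."""

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_paired_t_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = paired_t_test(sample(x, y))
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-6)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_pearson_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = pearson_r(sample(x, y))
        ref = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-6)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_ols_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        x, y = rng.normal(size=n), rng.normal(size=n)
        fit = linear_regression(sample(x, y))
        ref = sps.linregress(x, y)
        assert fit.slope == pytest.approx(float(ref.slope), abs=1e-9)
        assert fit.intercept == pytest.approx(float(ref.intercept), abs=1e-9)
        assert fit.r_squared == pytest.approx(float(ref.rvalue) ** 2, abs=1e-9)
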