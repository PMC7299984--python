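"""Statistical layer tests: Mann-Kendall, trend classes, RMA, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import thermodecay as td
from thermodecay.trends import (TREND_CLASS_NODATA, _mann_kendall_grid,
                                _tie_term)


def mk_brute_force(x):
    """Independent O(n^2) oracle for the Mann-Kendall statistic, variance
    (tie-corrected), continuity-corrected Z and two-sided normal p."""
    from collections import Counter
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(x[j] - x[i]))
    tie = sum(t * (t - 1) * (2 * t + 5) for t in Counter(x.tolist()).values())
    var = (n * (n - 1) * (2 * n + 5) - tie) / 18.0
    if var <= 0:
        return s, 0.0, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    return s, var, z, 2 * sps.norm.sf(abs(z))


class TestMannKendall:
    def test_monotone_series_frozen_values(self):
        """[1,2,3,4]: all 6 pairs concordant; variance 26/3; Z and p from
        the continuity-corrected normal formula (computed by the brute
        oracle and frozen)."""
        mk = td.mann_kendall([1, 2, 3, 4], min_n=4)
        assert mk.s == 6
        assert mk.var_s == pytest.approx(8.6666667)
        assert mk.z == pytest.approx(1.6984156, rel=1e-6)
        assert mk.p == pytest.approx(0.0894294, rel=1e-5)

    def test_constant_series(self):
        mk = td.mann_kendall([5.0] * 12, min_n=10)
        assert (mk.s, mk.z, mk.p) == (0, 0.0, 1.0)

    def test_reversal_antisymmetry(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0, 5.0, 3.5]
        fwd = td.mann_kendall(x, min_n=10)
        rev = td.mann_kendall(x[::-1], min_n=10)
        assert rev.s == -fwd.s
        assert rev.p == pytest.approx(fwd.p)

    def test_below_min_n_gives_invalid(self):
        mk = td.mann_kendall([1.0, 2.0, np.nan], min_n=3)
        assert not mk.valid
        assert mk.n == 2

    def test_nan_gaps_removed(self):
        mk = td.mann_kendall([1, np.nan, 2, 3, np.nan, 4], min_n=4)
        assert mk.s == 6

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(-5, 5), min_size=3, max_size=50))
    def test_brute_force_oracle_equivalence(self, values):
        """Implementation agrees with an independent pairwise double loop
        on series with heavy ties."""
        x = np.asarray(values, dtype=float)
        mk = td.mann_kendall(x, min_n=3)
        s, var, z, p = mk_brute_force(x)
        assert mk.s == s
        assert mk.var_s == pytest.approx(var, abs=1e-9)
        assert mk.z == pytest.approx(z, abs=1e-9)
        assert mk.p == pytest.approx(p, abs=1e-9)

    def test_tie_correction_reduces_variance(self):
        tied = [1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0]
        with_corr = td.mann_kendall(tied, min_n=5, tie_correction=True)
        without = td.mann_kendall(tied, min_n=5, tie_correction=False)
        assert with_corr.var_s < without.var_s
        untied = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert td.mann_kendall(untied, min_n=5).var_s == \
            td.mann_kendall(untied, min_n=5, tie_correction=False).var_s

    def test_continuity_toggle(self):
        x = [1.0, 3.0, 2.0, 4.0, 6.0, 5.0, 7.0]
        with_c = td.mann_kendall(x, min_n=5, continuity=True)
        without = td.mann_kendall(x, min_n=5, continuity=False)
        assert abs(without.z) > abs(with_c.z)


class TestClassifyTrend:
    @pytest.mark.parametrize("s,p,label", [
        (10, 0.03, "increasing_p05"),
        (10, 0.07, "increasing_p10"),
        (-10, 0.03, "decreasing_p05"),
        (-10, 0.07, "decreasing_p10"),
        (10, 0.5, "none"),
        (-10, 0.2, "none"),
        (0, 1.0, "none"),
    ])
    def test_class_boundaries(self, s, p, label):
        mk = td.MKResult(s=s, var_s=10.0, z=0.0, p=p, n=15)
        assert td.classify_trend(mk).label == label

    def test_invalid_rejected(self):
        mk = td.MKResult(0, float("nan"), float("nan"), float("nan"), 3)
        with pytest.raises(ValueError):
            td.classify_trend(mk)


class TestTrendMap:
    def test_vectorized_matches_scalar_path(self):
        rng = np.random.default_rng(0)
        X = np.round(rng.normal(size=(15, 10, 7)), 1)  # rounding forces ties
        s, var, z, p, n = _mann_kendall_grid(X, 10, True, True)
        for i in range(10):
            for j in range(7):
                mk = td.mann_kendall(X[:, i, j], 10)
                assert mk.s == s[i, j]
                assert mk.var_s == pytest.approx(var[i, j])
                assert mk.p == pytest.approx(p[i, j])

    def test_single_layer_error(self, small_grid):
        stack = td.RasterStack(np.ones((1, 4, 4)), small_grid, ["2003"])
        with pytest.raises(ValueError):
            td.trend_map(stack, min_n=1)

    def test_insufficient_years_error(self, small_grid):
        vals = np.ones((5, 4, 4))
        stack = td.RasterStack(vals, small_grid,
                               [f"200{i}" for i in range(5)])
        with pytest.raises(ValueError, match="min_n"):
            td.trend_map(stack, min_n=10)

    def test_masked_pixels_get_nodata_class(self, small_grid):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(15, 4, 4))
        vals[:, 0, 0] = np.nan
        stack = td.RasterStack(vals, small_grid,
                               [f"{2003 + i}" for i in range(15)])
        result = td.trend_map(stack, min_n=10)
        assert result.codes[0, 0] == TREND_CLASS_NODATA

    def test_strong_trend_detected(self, small_grid):
        t = np.arange(15, dtype=float)
        vals = np.broadcast_to(t[:, None, None], (15, 4, 4)).copy()
        vals += np.random.default_rng(2).normal(0, 0.5, vals.shape)
        stack = td.RasterStack(vals, small_grid,
                               [f"{2003 + i}" for i in range(15)])
        result = td.trend_map(stack, min_n=10)
        assert result.class_counts["increasing_p05"] == 16

    def test_zero_trend_type_one_rate(self):
        """On pure white noise, the p<0.05 detection fraction sits near the
        nominal level (binomial tolerance, 2500 pixels)."""
        g = td.GridSpec(50, 50, transform=(1.0, 0, 0, 0, -1.0, 50.0))
        vals = np.random.default_rng(3).normal(size=(15, 50, 50))
        stack = td.RasterStack(vals, g, [f"{2003 + i}" for i in range(15)])
        result = td.trend_map(stack, min_n=10)
        frac = (result.class_counts["increasing_p05"]
                + result.class_counts["decreasing_p05"]) / 2500
        assert 0.03 <= frac <= 0.07


class TestRMA:
    def test_exact_linear_data(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = td.rma_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_negative_slope(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        fit = td.rma_regression(x, -3 * x)
        assert fit.slope == pytest.approx(-3.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_axis_swap_reciprocal_and_scale_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(scale=0.2, size=20)
        fit = td.rma_regression(x, y)
        swapped = td.rma_regression(y, x)
        assert swapped.slope == pytest.approx(1.0 / fit.slope, rel=1e-10)
        scaled = td.rma_regression(x, c * y)
        assert scaled.slope == pytest.approx(c * fit.slope, rel=1e-10)

    def test_slope_sign_matches_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = -x + rng.normal(scale=0.3, size=30)
        fit = td.rma_regression(x, y)
        assert np.sign(fit.slope) == np.sign(fit.pearson_r)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            td.rma_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            td.rma_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationTable:
    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 6))
        table = td.correlation_table({"a": a, "b": a + rng.normal(size=(6, 6)),
                                      "c": rng.normal(size=(6, 6))})
        for m in (table.pearson, table.spearman):
            np.testing.assert_allclose(np.diag(m.values), 1.0)
            np.testing.assert_allclose(m.values, m.values.T)
            assert np.all(np.abs(m.values) <= 1 + 1e-12)

    def test_monotone_nonlinear_relation(self):
        """y = exp(x): perfectly monotone (Spearman 1) but not linear
        (Pearson < 1)."""
        x = np.linspace(0, 5, 36).reshape(6, 6)
        table = td.correlation_table({"x": x, "y": np.exp(x)})
        assert table.spearman.loc["x", "y"] == pytest.approx(1.0)
        assert table.pearson.loc["x", "y"] < 1.0

    def test_spearman_is_pearson_of_ranks(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 8))
        y = rng.normal(size=(8, 8))
        table = td.correlation_table({"x": x, "y": y})
        rx = sps.rankdata(x.ravel())
        ry = sps.rankdata(y.ravel())
        assert table.spearman.loc["x", "y"] == pytest.approx(
            sps.pearsonr(rx, ry).statistic, rel=1e-12)

    def test_pairwise_complete_deletion(self):
        x = np.array([[1.0, 2, 3, 4, 5, 6]])
        y = np.array([[2.0, 4, 6, 8, 10, 12]])
        z = np.array([[1.0, np.nan, np.nan, np.nan, 5, 6]])
        table = td.correlation_table({"x": x, "y": y, "z": z})
        assert table.n_pixels.loc["x", "y"] == 6
        assert table.n_pixels.loc["x", "z"] == 3
        assert table.pearson.loc["x", "y"] == pytest.approx(1.0)

    def test_mask_and_insufficient_pixels(self):
        x = np.arange(9.0).reshape(3, 3)
        y = x ** 2
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, :2] = True  # only two pixels survive
        table = td.correlation_table({"x": x, "y": y}, mask=mask)
        assert np.isnan(table.pearson.loc["x", "y"])


def test_tie_term_helper():
    # one pair + one triple: 2*1*9 + 3*2*11 = 84
    assert _tie_term(np.array([1.0, 1, 2, 2, 2, 3])) == 84.0
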