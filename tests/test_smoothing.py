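"""Optimal-segments smoother: exactness, continuity, selection, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clamptrace.smoothing import (
    OptimalSegmentsSmoother,
    eval_smooth,
    fit_optimal_segments,
)


def bruteforce_rss(t, y, knots):
    """Independent reference fit via the cubic Hermite parameterization.

    A C1 piecewise cubic on fixed knots is exactly parameterized by its
    values and slopes at the knots (2(k+1) free numbers), so an ordinary
    unconstrained least squares on the Hermite basis is the optimum of the
    same function space the smoother searches — by a different route."""
    n = len(t)
    knots = np.asarray(knots, dtype=float)
    k = len(knots) - 1
    seg = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, k - 1)
    A = np.zeros((n, 2 * (k + 1)))
    for i in range(n):
        j = seg[i]
        h = knots[j + 1] - knots[j]
        s = (t[i] - knots[j]) / h
        A[i, 2 * j] = 2 * s ** 3 - 3 * s ** 2 + 1          # value, left knot
        A[i, 2 * j + 1] = (s ** 3 - 2 * s ** 2 + s) * h    # slope, left knot
        A[i, 2 * j + 2] = -2 * s ** 3 + 3 * s ** 2         # value, right knot
        A[i, 2 * j + 3] = (s ** 3 - s ** 2) * h            # slope, right knot
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    r = y - A @ beta
    return float(r @ r)


def piecewise_signal(t):
    """Quadratic ramp followed by a steep sigmoid (non-cubic overall)."""
    return np.where(t < 90, 0.002 * t ** 2,
                    0.002 * 90 ** 2 + 30.0 / (1 + np.exp(-(t - 130) / 8.0)))


class TestExactness:
    def test_single_cubic_reproduced_exactly(self):
        t = np.arange(0.0, 181.0, 10.0)
        y = 1e-3 * t ** 3 - 0.05 * t ** 2 + 2 * t + 90
        curve = fit_optimal_segments(t, y, sigma=1e-6)
        val, der = eval_smooth(curve, t)
        assert curve.n_segments == 1
        assert np.abs(val - y).max() < 1e-8
        assert np.abs(der - (3e-3 * t ** 2 - 0.1 * t + 2)).max() < 1e-6

    def test_constant_data_flat_curve(self):
        t = np.arange(0.0, 121.0, 10.0)
        curve = fit_optimal_segments(t, np.full_like(t, 100.0), sigma=0.0)
        q = np.linspace(0, 120, 37)
        assert curve.n_segments == 1
        assert np.allclose(curve.value(q), 100.0, atol=1e-9)
        assert np.abs(curve.derivative(q)).max() < 1e-9

    def test_linear_value_and_slope(self):
        t = np.arange(0.0, 61.0, 10.0)
        curve = fit_optimal_segments(t, 3 * t + 5)
        assert curve.value([10.0])[0] == pytest.approx(35.0, abs=1e-8)
        assert curve.derivative([10.0])[0] == pytest.approx(3.0, abs=1e-8)

    def test_quadratic_derivative(self):
        t = np.arange(0.0, 101.0, 10.0)
        curve = fit_optimal_segments(t, t ** 2)
        assert curve.derivative([50.0])[0] == pytest.approx(100.0, abs=1e-6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(coeffs=st.lists(st.floats(-2.0, 2.0), min_size=4, max_size=4))
    def test_any_cubic_is_representable(self, coeffs):
        t = np.linspace(0.0, 10.0, 15)
        y = np.polyval(coeffs, t)
        curve = fit_optimal_segments(t, y)
        scale = max(np.abs(y).max(), 1.0)
        assert np.abs(curve.value(t) - y).max() < 1e-8 * scale


class TestStructure:
    def test_c1_continuity_at_interior_knots(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 301.0, 10.0)
        y = piecewise_signal(t) + rng.normal(0, 2, t.shape)
        curve = fit_optimal_segments(t, y, n_segments=5)
        # evaluate each interior knot from both adjacent polynomial pieces
        for j in range(1, curve.n_segments):
            h = curve.knots[j] - curve.knots[j - 1]
            left = np.polyval(curve.coefficients[:, j - 1], h)
            right = np.polyval(curve.coefficients[:, j], 0.0)
            dleft = np.polyval(np.polyder(curve.coefficients[:, j - 1]), h)
            dright = np.polyval(np.polyder(curve.coefficients[:, j]), 0.0)
            assert left == pytest.approx(right, rel=1e-9, abs=1e-9)
            assert dleft == pytest.approx(dright, rel=1e-9, abs=1e-9)

    def test_knots_span_data_and_increase(self):
        t = np.arange(0.0, 301.0, 10.0)
        curve = fit_optimal_segments(t, np.sin(t / 40), n_segments=4)
        assert curve.knots[0] == t[0] and curve.knots[-1] == t[-1]
        assert np.all(np.diff(curve.knots) > 0)

    def test_derivative_matches_finite_difference(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 301.0, 10.0)
        y = piecewise_signal(t) + rng.normal(0, 2, t.shape)
        curve = fit_optimal_segments(t, y)
        h = 1e-4
        q = np.linspace(5.0, 295.0, 40)
        fd = (curve.value(q + h) - curve.value(q - h)) / (2 * h)
        der = curve.derivative(q)
        scale = np.maximum(np.abs(fd), 1e-3)
        assert np.max(np.abs(der - fd) / scale) < 1e-4

    def test_scaling_linearity_with_fixed_knots(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 301.0, 10.0)
        y = piecewise_signal(t) + rng.normal(0, 2, t.shape)
        c1 = fit_optimal_segments(t, y, n_segments=4)
        c7 = fit_optimal_segments(t, 7.0 * y, n_segments=4)
        q = np.linspace(0, 300, 61)
        assert np.allclose(7.0 * c1.value(q), c7.value(q), rtol=1e-9, atol=1e-9)


class TestSelection:
    def test_rss_non_increasing_in_k(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 301.0, 10.0)
        y = piecewise_signal(t) + rng.normal(0, 2, t.shape)
        rss = [fit_optimal_segments(t, y, n_segments=k).rss for k in range(1, 7)]
        assert all(rss[i + 1] <= rss[i] + 1e-9 for i in range(len(rss) - 1))

    def test_noisy_piecewise_selects_multiple_segments(self):
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 301.0, 10.0)
        y = piecewise_signal(t) + rng.normal(0, 2, t.shape)
        curve = fit_optimal_segments(t, y, max_segments=6)
        assert curve.n_segments > 1
        # selected fit's RSS within 20% of the exhaustive-search optimum
        best = min(bruteforce_rss(t, y, fit_optimal_segments(t, y, n_segments=k).knots)
                   for k in range(1, 7))
        assert curve.rss <= 1.2 * best

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_fixed_k_matches_bruteforce_reference(self, k):
        rng = np.random.default_rng(k)
        t = np.arange(0.0, 301.0, 10.0)
        y = piecewise_signal(t) + rng.normal(0, 2, t.shape)
        curve = fit_optimal_segments(t, y, n_segments=k)
        assert curve.rss == pytest.approx(bruteforce_rss(t, y, curve.knots),
                                          rel=1e-8)

    def test_known_zero_sigma_uses_all_segments_when_misfit(self):
        t = np.arange(0.0, 301.0, 10.0)
        y = piecewise_signal(t)  # not cubic: misfit at any small k
        c_exact = fit_optimal_segments(t, y, sigma=0.0, max_segments=6)
        c_ftest = fit_optimal_segments(t, y, sigma="estimate", max_segments=6)
        assert c_exact.n_segments >= c_ftest.n_segments


class TestErrors:
    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="insufficient data"):
            fit_optimal_segments(np.arange(5.0), np.arange(5.0))

    def test_unsorted_input(self):
        t = np.array([0.0, 10, 5, 20, 30, 40])
        with pytest.raises(ValueError, match="unsorted"):
            fit_optimal_segments(t, np.zeros(6))

    def test_extrapolation_refused(self):
        t = np.arange(0.0, 61.0, 10.0)
        curve = fit_optimal_segments(t, t)
        with pytest.raises(ValueError, match="extrapolation"):
            curve.value([70.0])

    def test_sklearn_estimator_api(self):
        t = np.arange(0.0, 61.0, 10.0)
        sm = OptimalSegmentsSmoother(max_segments=3).fit(t, 2 * t)
        assert sm.n_segments_ == 1
        assert sm.get_params()["max_segments"] == 3
        assert np.allclose(sm.predict(t), 2 * t, atol=1e-8)
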