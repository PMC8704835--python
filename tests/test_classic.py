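"""Penalized-least-squares family, iterative median filter, rolling circle."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import specbase as sb
from specbase.classic import pls_solve, second_difference_matrix
from specbase.core import SingularSystemError


def dense_pls_oracle(x, w, lam):
    """Reference solve of (W + lam D'D) b = W x with dense linear algebra."""
    p = x.size
    D = second_difference_matrix(p).toarray()
    A = np.diag(w) + lam * (D.T @ D)
    return np.linalg.solve(A, w * x)


class TestPlsSolve:
    def test_second_difference_annihilates_affine(self):
        D = second_difference_matrix(10).toarray()
        np.testing.assert_array_equal(D @ np.ones(10), 0)
        np.testing.assert_array_equal(D @ np.arange(10.0), 0)

    def test_constant_input_is_fixed_point(self, rng):
        x = np.full(30, 7.5)
        w = rng.random(30)
        np.testing.assert_allclose(pls_solve(x, w, 5.0), x, atol=1e-10)

    def test_hand_solved_three_channel_system(self):
        b = pls_solve(np.array([0.0, 1.0, 0.0]), np.ones(3), 1.0)
        np.testing.assert_allclose(b, np.array([2, 3, 2]) / 7, atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        for _ in range(25):
            p = int(rng.integers(5, 61))
            x = rng.normal(0, 10, p)
            w = rng.random(p)
            lam = float(10 ** rng.uniform(-2, 6))
            np.testing.assert_allclose(
                pls_solve(x, w, lam), dense_pls_oracle(x, w, lam), atol=1e-8
            )

    def test_stiff_limit_is_straight_line_fit(self, rng):
        x = rng.normal(0, 1, 50) + np.linspace(0, 3, 50)
        A = np.vstack([np.ones(50), np.arange(50.0)]).T
        line = A @ np.linalg.lstsq(A, x, rcond=None)[0]
        b = pls_solve(x, np.ones(50), 1e12)
        assert np.max(np.abs(b - line)) < 1e-6

    def test_all_zero_weights_rejected(self):
        with pytest.raises(SingularSystemError):
            pls_solve(np.ones(10), np.zeros(10), 1.0)

    def test_weights_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            pls_solve(np.ones(5), np.full(5, 1.5), 1.0)


def _peak_on_line(p=200, height=100.0):
    x = np.linspace(10, 30, p)
    x[90:110] += height * np.exp(-0.5 * ((np.arange(90, 110) - 100) / 4) ** 2)
    return sb.Spectrum(sb.make_grid(0, p - 1, p), x)


class TestALS:
    def test_weight_assignment_after_one_update(self):
        x = _peak_on_line()
        res = sb.als_baseline(x, lam=1000, alpha=0.01, max_iter=2)
        w = res.diagnostics["weights"]
        above = x.values >= res.baseline.values
        # pattern from the final update: alpha above, 1 - alpha below
        assert set(np.round(w, 6)) <= {0.01, 0.99}
        np.testing.assert_array_equal(w == 0.01, above)

    def test_constant_input_converges_to_itself(self):
        x = sb.Spectrum(sb.make_grid(0, 9, 10), np.full(10, 3.0))
        res = sb.als_baseline(x)
        assert res.converged
        np.testing.assert_allclose(res.baseline.values, 3.0, atol=1e-10)

    def test_baseline_stays_below_peak(self):
        x = _peak_on_line()
        res = sb.als_baseline(x, lam=1000, alpha=0.01)
        apex = int(np.argmax(x.values))
        peak_height = x.values[apex] - np.interp(apex, [0, 199], [10, 30])
        assert x.values[apex] - res.baseline.values[apex] >= 0.9 * peak_height

    def test_alpha_outside_recommended_range_warns(self):
        x = _peak_on_line()
        with pytest.warns(UserWarning, match="recommended"):
            sb.als_baseline(x, alpha=0.3, max_iter=2)


class TestAirPLS:
    def test_zero_weight_at_or_above_baseline(self):
        x = _peak_on_line()
        res = sb.airpls_baseline(x, lam=50, max_iter=3)
        w = res.diagnostics["weights"]
        above = x.values >= res.baseline.values
        # weights reflect the previous iterate's pattern; all weights valid
        assert np.all((w >= 0) & (w <= 1))
        assert np.any(w == 0)

    def test_constant_input_terminates_immediately(self):
        x = sb.Spectrum(sb.make_grid(0, 9, 10), np.full(10, 4.0))
        res = sb.airpls_baseline(x)
        assert res.converged and res.n_iter == 1
        np.testing.assert_allclose(res.baseline.values, 4.0, atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_weights_bounded_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        x = sb.Spectrum(sb.make_grid(0, 49, 50), r.normal(50, 5, 50))
        res = sb.airpls_baseline(x, lam=10, max_iter=10)
        w = res.diagnostics["weights"]
        assert np.all(w >= 0) and np.all(w <= 1)


class TestArPLS:
    def test_unit_weight_below_baseline(self):
        x = _peak_on_line()
        r = np.random.default_rng(0)
        x = x.with_values(x.values + r.normal(0, 1, x.grid.p))
        res = sb.arpls_baseline(x, lam=200)
        w = res.diagnostics["weights"]
        below = x.values < res.baseline.values
        assert np.all(w[below] == 1.0)
        assert np.all((w >= 0) & (w <= 1))

    def test_logistic_half_point(self):
        # a residual equal to 2*sigma - mean of the negative part maps to 1/2
        d = np.array([-3.0, -1.0, 1.0, 2.0, 5.0])
        dneg = d[d < 0]
        m, s = dneg.mean(), dneg.std()
        target = 2 * s - m
        w = 1.0 / (1.0 + np.exp(2 * (target + m - 2 * s) / s))
        assert w == pytest.approx(0.5)

    def test_weight_shift_equivariance(self):
        x = _peak_on_line()
        r = np.random.default_rng(1)
        noisy = x.values + r.normal(0, 1, x.grid.p)
        w1 = sb.arpls_baseline(x.with_values(noisy), max_iter=5).diagnostics["weights"]
        w2 = sb.arpls_baseline(x.with_values(noisy + 500.0), max_iter=5).diagnostics["weights"]
        np.testing.assert_allclose(w1, w2, atol=1e-9)

    def test_noiseless_input_flags_degenerate_weights(self):
        x = sb.Spectrum(sb.make_grid(0, 9, 10), np.full(10, 2.0))
        res = sb.arpls_baseline(x)
        assert res.converged
        assert res.diagnostics["degenerate_weights"]


class TestIMF:
    def test_constant_is_fixed_point(self):
        x = sb.Spectrum(sb.make_grid(0, 99, 100), np.full(100, 6.0))
        res = sb.imf_baseline(x, window_cm=10, n_iter=3)
        np.testing.assert_array_equal(res.baseline.values, x.values)

    def test_isolated_spike_removed(self):
        g = sb.make_grid(0, 4, 5)
        x = sb.Spectrum(g, np.array([0.0, 0, 5, 0, 0]))
        res = sb.imf_baseline(x, window_cm=3, n_iter=1)
        np.testing.assert_array_equal(res.baseline.values, np.zeros(5))

    def test_iteration_is_contractive(self, rng):
        g = sb.make_grid(0, 199, 200)
        v = np.cumsum(rng.normal(0, 1, 200)) + 50
        prev = v.copy()
        changes = []
        import scipy.ndimage

        for _ in range(5):
            cur = scipy.ndimage.median_filter(prev, size=11, mode="reflect")
            changes.append(np.max(np.abs(cur - prev)))
            prev = cur
        assert all(b <= a + 1e-12 for a, b in zip(changes, changes[1:]))

    def test_window_wider_than_spectrum_rejected(self):
        x = sb.Spectrum(sb.make_grid(0, 9, 10), np.ones(10))
        with pytest.raises(ValueError):
            sb.imf_baseline(x, window_cm=50)


class TestRCF:
    def test_affine_ramp_reproduced(self):
        g = sb.make_grid(0, 199, 200)
        x = sb.Spectrum(g, 2.0 * g.nu + 5)
        res = sb.rcf_baseline(x, radius_cm=20)
        assert np.max(np.abs(res.baseline.values - x.values)) <= 1.0

    def test_narrow_spike_bridged(self):
        g = sb.make_grid(0, 200, 201)
        v = np.zeros(201)
        v[99:102] = 100.0
        res = sb.rcf_baseline(sb.Spectrum(g, v), radius_cm=50)
        assert res.baseline.values.max() < 5.0

    def test_baseline_is_lower_envelope(self, rng):
        g = sb.make_grid(0, 99, 100)
        x = sb.Spectrum(g, rng.normal(50, 10, 100))
        res = sb.rcf_baseline(x, radius_cm=10)
        assert np.all(res.baseline.values <= x.values + 1e-9)

    def test_excessive_radius_rejected(self):
        x = sb.Spectrum(sb.make_grid(0, 9, 10), np.ones(10))
        with pytest.raises(ValueError):
            sb.rcf_baseline(x, radius_cm=8.0)


@pytest.mark.parametrize(
    "corrector",
    [
        lambda x: sb.als_baseline(x, max_iter=10),
        lambda x: sb.airpls_baseline(x, max_iter=10),
        lambda x: sb.arpls_baseline(x, max_iter=10),
        lambda x: sb.imf_baseline(x, window_cm=30),
        lambda x: sb.rcf_baseline(x, radius_cm=20),
    ],
    ids=["als", "airpls", "arpls", "imf", "rcf"],
)
def test_corrected_plus_baseline_is_input(corrector, rng):
    g = sb.make_grid(0, 399, 400)
    x = sb.Spectrum(g, np.abs(rng.normal(100, 20, 400)) + 50)
    res = corrector(x)
    np.testing.assert_allclose(
        res.corrected.values + res.baseline.values, x.values, rtol=1e-12, atol=1e-9
    )
    assert res.baseline.values.size == g.p


@pytest.mark.parametrize(
    "corrector",
    [sb.als_baseline, sb.airpls_baseline, sb.arpls_baseline],
    ids=["als", "airpls", "arpls"],
)
def test_pure_smooth_curve_recovered(corrector, grid947):
    """A peak-free noiseless smooth curve is its own baseline."""
    curve = 500 + 400 * np.exp(-(((grid947.nu - 1500) / 900) ** 2))
    res = corrector(sb.Spectrum(grid947, curve))
    err = np.max(np.abs(res.baseline.values - curve)) / np.max(np.abs(curve))
    assert err < 0.02
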