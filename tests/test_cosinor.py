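"""Damped-cosinor model, fit, zero-amplitude test and rhythmicity call."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circakit.cosinor import (
    RhythmConfig,
    TimeSeries,
    classify_rhythmic,
    damped_cosinor,
    fit_damped_cosinor,
    normalize_amplitude_phase,
    zero_amplitude_test,
)

from conftest import grid_search_ssres, make_series


class TestModel:
    @pytest.mark.parametrize("t", [0.0, 5.0, 17.3, 100.0])
    def test_zero_amplitude_gives_baseline(self, t):
        assert damped_cosinor(t, B=5.0, A=0.0, k=0.0, T=24.0, P=0.0) == 5.0

    def test_quarter_period_peak(self):
        assert damped_cosinor(6.0, B=0.0, A=2.0, k=0.0, T=24.0, P=0.0) == \
            pytest.approx(2.0)

    def test_damped_value_matches_hand_arithmetic(self):
        # closed form at t=3: 1 + 2 e^{-0.15} sin(pi/4 + pi/6) = 2.6627601266
        val = damped_cosinor(3.0, B=1.0, A=2.0, k=0.05, T=24.0, P=math.pi / 6)
        assert val == pytest.approx(2.6627601266, abs=1e-9)

    def test_literal_damping_is_k_equal_one(self):
        t = np.array([0.5, 1.0, 2.0])
        lit = damped_cosinor(t, 0.0, 1.0, 1.0, 24.0, 0.3)
        byhand = np.exp(-t) * np.sin(2 * np.pi * t / 24.0 + 0.3)
        np.testing.assert_allclose(lit, byhand, rtol=1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(B=np.nan, A=1, k=0, T=24, P=0),
        dict(B=0, A=1, k=-0.1, T=24, P=0),
        dict(B=0, A=1, k=0, T=0, P=0),
        dict(B=0, A=np.inf, k=0, T=24, P=0),
    ])
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            damped_cosinor(1.0, **kwargs)


class TestTimeSeries:
    def test_requires_four_distinct_times(self):
        with pytest.raises(ValueError, match="4 distinct"):
            TimeSeries.build([0, 4, 8], [1, 2, 3])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            TimeSeries.build([0, 4, 8, 12], [1, np.nan, 3, 4])

    def test_replicate_means(self):
        ts = TimeSeries.build([0, 4, 0, 4, 8, 12], [1, 2, 3, 4, 5, 6],
                              ["a", "a", "b", "b", "b", "b"])
        t, m = ts.replicate_means()
        np.testing.assert_allclose(t, [0, 4, 8, 12])
        np.testing.assert_allclose(m, [2, 3, 5, 6])
        assert ts.n_replicates == 2


class TestFit:
    @pytest.mark.parametrize("truth", [
        dict(B=100.0, A=30.0, k=0.0, P=1.0),
        dict(B=-5.0, A=12.0, k=0.05, P=4.5),
        dict(B=0.7, A=0.2, k=0.12, P=0.1),
    ])
    def test_exact_recovery_on_noiseless_data(self, truth):
        ts = make_series(**truth, noise_sd=0.0,
                         times=np.arange(2.0, 39.0, 4.0))
        fit = fit_damped_cosinor(ts, fit_damping=True)
        assert fit.baseline == pytest.approx(truth["B"], rel=1e-4, abs=1e-6)
        assert fit.amplitude == pytest.approx(truth["A"], rel=1e-4)
        assert fit.damping_rate == pytest.approx(truth["k"], rel=1e-3, abs=1e-5)
        assert fit.phase == pytest.approx(truth["P"], rel=1e-4)
        assert fit.r_squared >= 1 - 1e-8

    def test_constant_series_rejected(self):
        ts = TimeSeries.build([2, 6, 10, 14], [7.0, 7.0, 7.0, 7.0])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_damped_cosinor(ts)

    def test_too_few_points_rejected(self):
        ts = TimeSeries.build([0, 6, 12, 18], [1.0, 2.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="free parameters"):
            fit_damped_cosinor(ts, fit_damping=True)  # 4 points, 4 params

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6, 7, 8])
    def test_ssres_matches_grid_search_oracle(self, seed):
        """On seeded 8-point noisy series the nonlinear fit attains the
        global minimum located by an exhaustive phase-grid oracle."""
        ts = make_series(A=15.0, noise_sd=12.0, seed=seed)
        fit = fit_damped_cosinor(ts, fit_damping=False)
        oracle = grid_search_ssres(*ts.replicate_means())
        assert fit.ss_residual <= oracle * (1 + 1e-9)
        assert fit.ss_residual == pytest.approx(oracle, rel=1e-6)

    def test_period_is_fixed_not_fitted(self):
        ts = make_series(noise_sd=5.0, seed=9)
        fit = fit_damped_cosinor(ts, period=26.0, fit_damping=False)
        assert fit.period == 26.0

    def test_literal_mode_freezes_k_at_one(self):
        ts = make_series(noise_sd=5.0, seed=10)
        fit = fit_damped_cosinor(ts, fit_damping=False, k_fixed=1.0)
        assert fit.damping_rate == 1.0
        assert "damping_rate" not in fit.param_se

    def test_dof_bookkeeping(self):
        ts = make_series(noise_sd=5.0, seed=11, n_replicates=3)
        fit = fit_damped_cosinor(ts, fit_damping=True)
        assert fit.n_points == 8          # replicate means on the 8-point grid
        assert fit.dof == 8 - 4
        fit_all = fit_damped_cosinor(ts, fit_damping=True,
                                     fit_replicate_means=False)
        assert fit_all.n_points == 24
        assert fit_all.dof == 24 - 4

    def test_r_squared_identity(self):
        ts = make_series(noise_sd=8.0, seed=12)
        fit = fit_damped_cosinor(ts)
        assert fit.r_squared == pytest.approx(
            1 - fit.ss_residual / fit.ss_total, abs=1e-12)


class TestInvariants:
    @given(A=st.floats(0.5, 50), P=st.floats(0, 2 * math.pi - 1e-9))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_phase_normalization_idempotent(self, A, P):
        assert normalize_amplitude_phase(A, P) == \
            pytest.approx(normalize_amplitude_phase(-A, P + math.pi))
        An, Pn = normalize_amplitude_phase(A, P)
        assert An >= 0 and 0 <= Pn < 2 * math.pi

    def test_sign_flipped_generator_gives_identical_fit(self):
        t = np.arange(2.0, 31.0, 4.0)
        y1 = 10 + 4 * np.sin(2 * np.pi * t / 24 + 1.0)
        y2 = 10 + (-4) * np.sin(2 * np.pi * t / 24 + 1.0 + np.pi)
        np.testing.assert_allclose(y1, y2, atol=1e-12)
        f1 = fit_damped_cosinor(TimeSeries.build(t, y1), fit_damping=False)
        f2 = fit_damped_cosinor(TimeSeries.build(t, y2), fit_damping=False)
        assert f1.amplitude == pytest.approx(f2.amplitude, rel=1e-8)
        assert f1.phase == pytest.approx(f2.phase, rel=1e-6)

    @pytest.mark.parametrize("scale,shift", [(2.5, 0.0), (0.3, 40.0),
                                             (10.0, -7.0)])
    def test_r_squared_invariant_under_affine_rescaling(self, scale, shift):
        ts = make_series(noise_sd=10.0, seed=21)
        fit = fit_damped_cosinor(ts, fit_damping=False)
        ts2 = TimeSeries(times=ts.times, values=scale * ts.values + shift,
                         replicates=ts.replicates, series_id="scaled")
        fit2 = fit_damped_cosinor(ts2, fit_damping=False)
        assert fit2.r_squared == pytest.approx(fit.r_squared, abs=1e-9)


class TestZeroAmplitude:
    def test_noiseless_rhythmic_fit_is_significant(self):
        ts = make_series(A=20.0, noise_sd=0.0)
        fit = fit_damped_cosinor(ts, fit_damping=False)
        res = zero_amplitude_test(fit)
        # residual variance ~ 0 so the ellipse collapses onto A > 0
        assert res.significant
        assert res.ci_low > 0

    def test_flat_noisy_series_not_significant(self):
        ts = make_series(A=0.0, noise_sd=10.0, seed=31)
        fit = fit_damped_cosinor(ts, fit_damping=False)
        res = zero_amplitude_test(fit)
        assert not res.significant
        assert res.ci_low == 0.0

    def test_requires_dof(self):
        ts = make_series(A=10.0, noise_sd=1.0, seed=32,
                         times=[2.0, 6.0, 10.0, 14.0])
        fit = fit_damped_cosinor(ts, fit_damping=False)  # dof = 1, fine
        zero_amplitude_test(fit)

    def test_null_rejection_rate_calibrated(self):
        """Type-I error of the default zero-amplitude test on pure-noise
        series stays within 3 Monte-Carlo SE of alpha (500 replicates here;
        the acceptance suite runs the full 1000)."""
        n, alpha = 500, 0.05
        rej = 0
        for i in range(n):
            ts = make_series(A=0.0, B=10.0, noise_sd=3.0, seed=10_000 + i)
            fit = fit_damped_cosinor(ts, fit_damping=False)
            rej += zero_amplitude_test(fit, alpha=alpha).significant
        mc_se = math.sqrt(alpha * (1 - alpha) / n)
        assert abs(rej / n - alpha) <= 3 * mc_se

    def test_wald_interval_available(self):
        ts = make_series(A=30.0, noise_sd=5.0, seed=33)
        fit = fit_damped_cosinor(ts, fit_damping=False)
        res = zero_amplitude_test(fit, method="wald")
        se = fit.param_se["amplitude"]
        import scipy.stats as st_
        tcrit = st_.t.ppf(0.975, fit.dof)
        assert res.ci_low == pytest.approx(fit.amplitude - tcrit * se)
        assert res.ci_high == pytest.approx(fit.amplitude + tcrit * se)


class TestClassify:
    def test_strong_rhythm_called_rhythmic(self):
        ts = make_series(A=30.0, noise_sd=3.0, seed=41)   # A / sigma = 10
        call = classify_rhythmic(ts, RhythmConfig(fit_damping=False))
        assert call.rhythmic and call.reason is None
        assert call.fit.r_squared > 0.55
        assert call.amplitude_test.ci_low > 0

    def test_white_noise_fails_r2_gate(self):
        # seeded noise draw whose best-fit R^2 is ~0.30, well below the gate
        ts = make_series(A=0.0, noise_sd=10.0, seed=62)
        call = classify_rhythmic(ts, RhythmConfig(fit_damping=False))
        assert not call.rhythmic
        assert call.fit.r_squared < 0.55
        assert "r2_gate" in call.reason

    def test_fit_error_propagates_as_reason(self):
        ts = TimeSeries.build([2, 6, 10, 14], [3.0, 3.0, 3.0, 3.0])
        call = classify_rhythmic(ts)
        assert not call.rhythmic
        assert call.reason == "fit_error"
        assert "zero-variance" in call.detail

    @pytest.mark.parametrize("seed", [101, 102, 103, 104, 105])
    def test_borderline_call_matches_independent_recomputation(self, seed):
        """Both gates recomputed from scratch with plain linear algebra
        (design-matrix projection + 2-df F test) must agree with the call."""
        ts = make_series(A=8.0, noise_sd=7.0, seed=seed)
        cfg = RhythmConfig(fit_damping=False)
        call = classify_rhythmic(ts, cfg)

        t, y = ts.replicate_means()
        omega = 2 * np.pi / cfg.period_h
        X = np.column_stack([np.ones_like(t), np.sin(omega * t),
                             np.cos(omega * t)])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ssres = float(resid @ resid)
        sstot = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - ssres / sstot
        dof = t.size - 3
        sigma2 = ssres / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        beta = coef[1:]
        F = beta @ np.linalg.solve(cov[1:, 1:], beta) / 2
        import scipy.stats as st_
        sig = F > st_.f.ppf(0.95, 2, dof)

        assert call.fit.r_squared == pytest.approx(r2, abs=1e-8)
        assert call.r2_pass == (r2 > 0.55)
        assert call.amplitude_pass == sig
        assert call.rhythmic == ((r2 > 0.55) and sig)
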