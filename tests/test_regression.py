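import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikephase as sp
from spikephase import (
    ChargeMatrix,
    PhaseResettingRegression,
    SpikeTrain,
    Trace,
    bin_charges,
    choose_n_bins,
    fit_prc,
    interpolated_phase,
)


class TestChooseNBins:
    @pytest.mark.parametrize(
        "mean_isi,d,expected",
        [(100.0, 1.0, 50), (40.0, 1.0, 40), (40.0, 2.0, 20), (1000.0, 1.0, 50)],
    )
    def test_rule(self, mean_isi, d, expected):
        assert choose_n_bins(mean_isi, d) == expected

    def test_too_short_isi(self):
        with pytest.raises(ValueError):
            choose_n_bins(1.5, 1.0)


class TestInterpolatedPhase:
    @pytest.mark.parametrize("t,expected", [(10.0, 0.0), (110.0, 1.0), (60.0, 0.5)])
    def test_endpoints_and_midpoint(self, t, expected):
        assert interpolated_phase(t, 10.0, 110.0) == pytest.approx(expected)

    def test_outside_interval(self):
        with pytest.raises(ValueError):
            interpolated_phase(5.0, 10.0, 110.0)

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None, derandomize=True)
    def test_bounded(self, frac):
        a, b = 3.0, 47.0
        assert 0.0 <= interpolated_phase(a + frac * (b - a), a, b) <= 1.0


def _train(times, span):
    return SpikeTrain(np.asarray(times, dtype=float), span)


class TestBinCharges:
    def test_zero_current(self):
        cur = Trace(0.0, 1.0, np.zeros(300))
        spikes = _train([0.0, 100.0, 210.0, 300.0], (0.0, 300.0))
        cm = bin_charges(cur, spikes, 10)
        assert not np.any(cm.Q)
        np.testing.assert_allclose(
            cm.y, np.diff(spikes.spike_times) / np.mean(np.diff(spikes.spike_times))
        )

    def test_constant_current_uniform_split(self):
        amp, n_bins = 7.0, 10
        cur = Trace(0.0, 1.0, np.full(400, amp))
        spikes = _train([0.0, 100.0, 250.0, 400.0], (0.0, 400.0))
        cm = bin_charges(cur, spikes, n_bins, "interpolated")
        for a, T in enumerate(np.diff(spikes.spike_times)):
            np.testing.assert_allclose(cm.Q[a], amp * T / n_bins, rtol=1e-12)

    def test_single_pulse_lands_in_its_bin(self):
        # pulse of amplitude A, duration 2 ms fully inside bin 3 (0-based 2)
        # of the ISI [0, 100): bin 2 spans [20, 30)
        A = 55.0
        samples = np.zeros(200)
        samples[24:26] = A
        cur = Trace(0.0, 1.0, samples)
        spikes = _train([0.0, 100.0, 200.0], (0.0, 200.0))
        cm = bin_charges(cur, spikes, 10, "interpolated")
        assert cm.Q[0, 2] == pytest.approx(A * 2.0)
        assert np.sum(np.abs(cm.Q)) == pytest.approx(A * 2.0)

    def test_interpolated_mode_conserves_charge_per_interval(self, noisy_run):
        cur, spikes = noisy_run
        cm = bin_charges(cur, spikes, 50, "interpolated")
        st_ = spikes.spike_times
        times = cur.times
        for a in (0, 5, len(st_) - 2):
            lo, hi = np.searchsorted(times, [st_[a], st_[a + 1]], side="left")
            total = np.sum(cur.samples[lo:hi]) * cur.dt
            assert np.sum(cm.Q[a]) == pytest.approx(total, rel=1e-9)

    def test_mean_period_discards_overflow(self):
        cur = Trace(0.0, 1.0, np.full(300, 2.0))
        # ISIs 80 and 220: mean 150; second interval overflows bin n
        spikes = _train([0.0, 80.0, 300.0], (0.0, 300.0))
        cm = bin_charges(cur, spikes, 10, "mean_period")
        assert np.sum(cm.Q[1]) == pytest.approx(2.0 * 150.0, rel=1e-9)


class TestFitPRC:
    def test_noiseless_linear_system_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n_isi, n_bins = 120, 8
        z = np.abs(rng.normal(2e-4, 1e-4, n_bins))
        Q = rng.normal(0.0, 30.0, (n_isi, n_bins))
        y = 1.0 - Q @ z
        cm = ChargeMatrix(Q, y, "interpolated", 100.0)
        res = fit_prc(cm)
        np.testing.assert_allclose(res.params, z, rtol=1e-8)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equation_algebra(self):
        # independent route: solve (X'X) b = X'y by hand and compute the
        # classical SEs from the residual variance
        rng = np.random.default_rng(1)
        n_isi, n_bins = 90, 6
        Q = rng.normal(0.0, 20.0, (n_isi, n_bins))
        y = 1.0 - Q @ np.full(n_bins, 1e-4) + rng.normal(0, 0.05, n_isi)
        res = fit_prc(ChargeMatrix(Q, y, "interpolated", 100.0))
        X = np.column_stack([np.ones(n_isi), Q])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        s2 = resid @ resid / (n_isi - n_bins - 1)
        np.testing.assert_allclose(res.params, -beta[1:], rtol=1e-9)
        np.testing.assert_allclose(res.bse, np.sqrt(s2 * np.diag(XtX_inv))[1:], rtol=1e-8)

    def test_row_permutation_leaves_fit_unchanged(self):
        rng = np.random.default_rng(2)
        Q = rng.normal(0.0, 20.0, (60, 5))
        y = 1.0 - Q @ np.full(5, 1e-4) + rng.normal(0, 0.02, 60)
        res = fit_prc(ChargeMatrix(Q, y, "interpolated", 100.0))
        perm = rng.permutation(60)
        res_p = fit_prc(ChargeMatrix(Q[perm], y[perm], "interpolated", 100.0))
        np.testing.assert_allclose(res.params, res_p.params, rtol=1e-10)
        np.testing.assert_allclose(res.bse, res_p.bse, rtol=1e-10)

    def test_null_data_coverage(self):
        # y independent of Q: nearly all coefficients within 3 SE of zero
        rng = np.random.default_rng(3)
        hits = []
        for _ in range(25):
            Q = rng.normal(0.0, 25.0, (80, 10))
            y = 1.0 + rng.normal(0, 0.1, 80)
            res = fit_prc(ChargeMatrix(Q, y, "interpolated", 100.0))
            hits.append(np.abs(res.params) < 3 * res.bse)
        assert np.mean(np.concatenate(hits)) >= 0.95

    def test_parameter_recovery_from_simulation(self, mc_prc):
        # moderate pulsed noise, ~1000 ISIs: most bins within 2 SE of truth
        cur = sp.generate_pulsed_noise(sp.NoiseSpec(1.0, 60.0, seed=5), 1_000_000.0, 1.0)
        res = sp.simulate_trajectory(mc_prc, 0.001, cur, 1.0, "restart", refine=True)
        fit = PhaseResettingRegression.from_traces(
            cur, res.spikes, "auto", "interpolated", pulse_ms=1.0
        ).fit()
        true_vals = mc_prc(fit.prc.bin_centers)
        assert np.mean(np.abs(fit.params - true_vals) <= 2 * fit.bse) >= 0.90

    def test_guards(self):
        rng = np.random.default_rng(4)
        Q = rng.normal(0.0, 1.0, (12, 6))
        with pytest.raises(ValueError, match="intervals"):
            PhaseResettingRegression(ChargeMatrix(Q, np.ones(12), "interpolated", 1.0))
        Qz = rng.normal(0.0, 1.0, (40, 4))
        Qz[:, 2] = 0.0
        with pytest.raises(ValueError, match="rank"):
            PhaseResettingRegression(ChargeMatrix(Qz, np.ones(40), "interpolated", 1.0))


class TestEstimatorProperties:
    def test_interpolated_beats_mean_period_se(self, noisy_run):
        cur, spikes = noisy_run
        fi = PhaseResettingRegression.from_traces(cur, spikes, "auto", "interpolated", pulse_ms=1.0).fit()
        fm = PhaseResettingRegression.from_traces(cur, spikes, "auto", "mean_period", pulse_ms=1.0).fit()
        assert fm.bse.mean() > fi.bse.mean()
        # the mean-period penalty concentrates at late phases
        late = slice(fi.n_bins * 3 // 4, None)
        early = slice(0, fi.n_bins // 4)
        gap = fm.bse - fi.bse
        assert gap[late].mean() > gap[early].mean()

    def test_sensitivity_stable_across_noise_amplitudes(self, mc_prc):
        # stability of the recovered sensitivity across noise amplitudes in
        # the estimator's validity regime (total CV up to ~0.3)
        ests = []
        for sig in (150.0, 300.0, 450.0):
            cur = sp.generate_pulsed_noise(sp.NoiseSpec(1.0, sig, seed=8), 600_000.0, 1.0)
            res = sp.simulate_trajectory(mc_prc, 0.001, cur, 1.0, "restart", refine=True)
            fit = PhaseResettingRegression.from_traces(
                cur, res.spikes, "auto", "interpolated", pulse_ms=1.0
            ).fit()
            ests.append(fit.sensitivity())
        ests = np.asarray(ests)
        assert np.ptp(ests) / np.mean(ests) < 0.20

    def test_r2_rises_then_saturates_with_sigma(self):
        # with intrinsic noise present, R^2 grows with sigma then flattens
        r2 = []
        for sig in (10.0, 60.0, 120.0):
            exp = sp.synth_experiment(sigma=sig, episode_ms=30_000.0, n_episodes=1, seed=21)
            ep = exp.episodes[0]
            fit = PhaseResettingRegression.from_traces(
                ep.current, ep.spikes, "auto", "interpolated", pulse_ms=0.5
            ).fit()
            r2.append(fit.rsquared)
        assert r2[0] < r2[1]
        assert abs(r2[2] - r2[1]) < 0.5 * (r2[1] - r2[0])

    def test_summary_mentions_key_fields(self, noisy_run):
        cur, spikes = noisy_run
        fit = PhaseResettingRegression.from_traces(cur, spikes, 20, "interpolated").fit()
        text = fit.summary()
        for token in ("R-squared", "intervals", "sensitivity", "centroid"):
            assert token in text
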