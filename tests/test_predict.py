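import numpy as np
import pytest
from scipy import stats

import spikephase as sp
from spikephase import (
    SpikeTrain,
    Trace,
    autocorrelogram,
    isi_cv,
    mean_rate,
    predict_spike_times,
    variance_explained,
)


class TestPredictSpikeTimes:
    def test_zero_current_predicts_mean_period(self, mc_prc):
        spikes = SpikeTrain(np.arange(0.0, 5000.0, 800.0), (0.0, 5000.0))
        cur = Trace(0.0, 1.0, np.zeros(5000))
        rep = predict_spike_times(mc_prc, 1 / 800.0, cur, spikes)
        np.testing.assert_allclose(rep.predicted_isis, 800.0, rtol=1e-9)

    def test_self_consistency_with_simulation(self, mc_prc):
        # data generated by the same phase model, PRC, rate and current with
        # no intrinsic noise: predictions reproduce the simulated ISIs
        omega = 0.001
        cur = sp.generate_pulsed_noise(sp.NoiseSpec(1.0, 300.0, 31), 100_000.0, 1.0)
        # grid-time spikes keep the predictor's steps aligned with the
        # generating integration, so agreement is within one step
        res = sp.simulate_trajectory(mc_prc, omega, cur, 1.0, "restart", refine=False)
        rep = predict_spike_times(mc_prc, omega, cur, res.spikes, dt=1.0)
        np.testing.assert_allclose(rep.predicted_isis, rep.actual_isis, atol=1.0 + 1e-9)
        assert rep.variance_explained > 0.999

    def test_unpredicted_interval_counted(self, mc_prc):
        # strong negative constant current with a type-1 PRC stalls phi
        spikes = SpikeTrain(np.array([0.0, 500.0, 1000.0]), (0.0, 2000.0))
        cur = Trace(0.0, 1.0, np.full(2000, -1e7))
        rep = predict_spike_times(mc_prc, 0.001, cur, spikes, dt=1.0)
        assert rep.n_unpredicted >= 1

    def test_omega_defaults_to_reciprocal_mean_isi(self, mc_prc):
        spikes = SpikeTrain(np.arange(0.0, 3000.0, 250.0), (0.0, 3000.0))
        cur = Trace(0.0, 1.0, np.zeros(3000))
        rep = predict_spike_times(mc_prc, None, cur, spikes)
        assert rep.omega_used == pytest.approx(1 / 250.0)


class TestVarianceExplained:
    def test_perfect_prediction(self):
        a = np.array([10.0, 12.0, 9.0, 14.0])
        assert variance_explained(a, a) == pytest.approx(1.0)

    def test_mean_prediction_zero(self):
        a = np.array([10.0, 12.0, 9.0, 14.0])
        p = np.full(4, a.mean())
        assert variance_explained(p, a) == pytest.approx(0.0, abs=1e-12)

    def test_additive_noise_expectation(self):
        # actual = predicted + noise(var v): E[VE] = 1 - v/Var(actual)
        rng = np.random.default_rng(12)
        n, v = 200, 4.0
        ves = []
        for _ in range(200):
            pred = rng.normal(100.0, 10.0, n)
            actual = pred + rng.normal(0.0, np.sqrt(v), n)
            ves.append(variance_explained(pred, actual))
        expected = 1.0 - v / (100.0 + v)
        assert np.mean(ves) == pytest.approx(expected, abs=0.01)

    def test_methods_agree_when_unbiased(self):
        rng = np.random.default_rng(4)
        pred = rng.normal(100.0, 10.0, 500)
        actual = pred + rng.normal(0.0, 2.0, 500)
        ss = variance_explained(pred, actual, "ss")
        corr = variance_explained(pred, actual, "corr")
        assert ss == pytest.approx(corr, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(np.ones(5), np.ones(5))


class TestISICV:
    def test_periodic_train_zero(self):
        st = SpikeTrain(np.arange(0.0, 1000.0, 100.0), (0.0, 1000.0))
        assert isi_cv(st) == 0.0

    def test_hand_arithmetic(self):
        assert isi_cv(np.array([1.0, 3.0, 1.0, 3.0])) == pytest.approx(
            np.std([1, 3, 1, 3], ddof=1) / 2.0
        )
        # two-interval example: mean 2, SD sqrt(2) -> 0.7071
        assert np.std([1.0, 3.0], ddof=1) / 2.0 == pytest.approx(0.7071, abs=1e-4)

    def test_exponential_isis_near_unity(self):
        rng = np.random.default_rng(9)
        isis = rng.exponential(50.0, 10_000)
        assert isi_cv(isis) == pytest.approx(1.0, abs=0.03)

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            isi_cv(np.array([1.0, 2.0]))


class TestAutocorrelogram:
    def test_single_spike_all_zero(self):
        st = SpikeTrain(np.array([10.0]), (0.0, 100.0))
        acg = autocorrelogram(st, 2.0, 50.0)
        assert not np.any(acg.counts)

    def test_periodic_train_peaks_at_multiples(self):
        T = 100.0
        st = SpikeTrain(np.arange(0.0, 5000.0, T), (0.0, 5000.0))
        acg = autocorrelogram(st, 2.0, 350.0)
        centers = (acg.bin_edges[:-1] + acg.bin_edges[1:]) / 2
        nonzero = centers[acg.counts > 0]
        assert np.all(np.isin(np.round(nonzero / T * 2), [2, 4, 6]))
        # lag T appears once per adjacent pair within range
        assert acg.counts[np.digitize(T, acg.bin_edges) - 1] == 49

    def test_poisson_train_flat(self):
        rng = np.random.default_rng(2)
        times = np.cumsum(rng.exponential(20.0, 4000))
        st = SpikeTrain(times, (0.0, float(times[-1]) + 1))
        acg = autocorrelogram(st, 10.0, 200.0)
        # chi-square uniformity test over the bins, alpha = 0.01
        chi2, p = stats.chisquare(acg.counts)
        assert p > 0.01

    def test_rate_normalization(self):
        st = SpikeTrain(np.arange(0.0, 1000.0, 100.0), (0.0, 1000.0))
        counts = autocorrelogram(st, 2.0, 300.0, "counts")
        rate = autocorrelogram(st, 2.0, 300.0, "rate")
        np.testing.assert_allclose(
            rate.counts, counts.counts / (st.n_spikes * 0.002)
        )


class TestMeanRate:
    def test_hand_example(self):
        st = SpikeTrain(np.array([0.0, 100.0, 200.0]), (0.0, 200.0))
        assert mean_rate(st) == pytest.approx(10.0)

    def test_single_spike_errors(self):
        with pytest.raises(ValueError):
            mean_rate(SpikeTrain(np.array([5.0]), (0.0, 10.0)))

    def test_simulated_rate_matches_omega(self, mc_prc):
        cur = Trace(0.0, 1.0, np.zeros(100_000))
        res = sp.simulate_trajectory(mc_prc, 0.01, cur, 1.0, "restart", refine=True)
        assert mean_rate(res.spikes) == pytest.approx(10.0, abs=0.01)
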