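"""Estimating the infinitesimal PRC from a noise-perturbed spike train.

The estimator treats each interspike interval (ISI) as one observation of a
multiple linear regression.  The interval is divided into n phase bins and
the injected charge delivered within each bin, Q_{a,i}, is a predictor; the
response is the interval length normalised by the mean interval,
y_a = T_a / T_mean.  Charge arriving where the PRC is positive advances
phase and shortens the interval, so the PRC values are the *negated*
regression coefficients, in cycles per pA*ms.

Two time-to-phase mappings are supported for binning the current:

* ``interpolated`` — phase of a sample is its time since the previous spike
  divided by the length of *that* interval (equalises estimation error
  across the cycle and conserves charge per interval);
* ``mean_period`` — time since the previous spike divided by the mean
  period (the traditional surrogate; late-phase estimates degrade because
  latent phase and time decouple as noise-driven variance accumulates).

The model/results split follows the statsmodels convention:
:class:`PhaseResettingRegression` is built from data and its ``fit()``
returns a :class:`PhaseResettingResults` carrying estimates, standard
errors, R^2, a ``summary()`` table, and prediction helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .io import SpikeTrain, Trace
from .prc import TabulatedPRC, centroid, sensitivity

__all__ = [
    "ChargeMatrix",
    "PhaseResettingRegression",
    "PhaseResettingResults",
    "choose_n_bins",
    "interpolated_phase",
    "bin_charges",
    "fit_prc",
]

#: minimum number of ISIs beyond the bin count required for a stable fit
MIN_EXTRA_INTERVALS = 10


def choose_n_bins(mean_isi: float, d: float) -> int:
    """Bin-count rule: one noise pulse per bin on average, capped at 50.

    n = min(floor(mean_isi / d), 50).  Keeping bins at least as long as a
    pulse preserves statistical independence of the per-bin charges.
    """
    if mean_isi <= 0 or d <= 0:
        raise ValueError("mean_isi and d must be positive")
    n = min(int(np.floor(mean_isi / d)), 50)
    if n < 2:
        raise ValueError(
            f"mean ISI ({mean_isi:g} ms) shorter than two pulses of {d:g} ms"
        )
    return n


def interpolated_phase(t: float, spike_prev: float, spike_next: float) -> float:
    """Interpolated phase: time since the previous spike divided by the
    length of that particular interspike interval."""
    if spike_next <= spike_prev:
        raise ValueError("spike_next must exceed spike_prev")
    if t < spike_prev or t > spike_next:
        raise ValueError("t outside the interspike interval")
    return (t - spike_prev) / (spike_next - spike_prev)


@dataclass(frozen=True)
class ChargeMatrix:
    """Per-ISI, per-phase-bin injected charge and normalised ISI lengths."""

    Q: np.ndarray  # (n_isi, n_bins), pA*ms
    y: np.ndarray  # T_a / mean(T), dimensionless
    binning_mode: str
    mean_isi: float

    @property
    def n_intervals(self) -> int:
        return self.Q.shape[0]

    @property
    def n_bins(self) -> int:
        return self.Q.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        n = self.n_bins
        return (np.arange(n) + 0.5) / n


def bin_charges(
    current: Trace,
    spikes: SpikeTrain,
    n_bins: int,
    mode: str = "interpolated",
) -> ChargeMatrix:
    """Integrate the injected current into per-phase-bin charges.

    Each dt-sample is assigned to the bin containing its start time (pulses
    straddling a bin edge are split by sample membership).  In mean-period
    mode, samples falling beyond bin n (ISIs longer than the mean period)
    are discarded; in interpolated mode every sample of an ISI lands in a
    bin, so row sums equal the total charge injected during the interval.
    """
    if mode not in ("interpolated", "mean_period"):
        raise ValueError("mode must be 'interpolated' or 'mean_period'")
    st = spikes.spike_times
    if st.size < 2:
        raise ValueError("need at least 2 spikes to form an interval")
    isis = np.diff(st)
    mean_isi = float(np.mean(isis))
    times = current.times
    dt = current.dt
    n_isi = isis.size
    Q = np.zeros((n_isi, n_bins))
    lo = np.searchsorted(times, st[:-1], side="left")
    hi = np.searchsorted(times, st[1:], side="left")
    for a in range(n_isi):
        if hi[a] <= lo[a]:
            raise ValueError(
                f"interval {a} ({isis[a]:g} ms) shorter than one current sample"
            )
        ts = times[lo[a] : hi[a]]
        denom = isis[a] if mode == "interpolated" else mean_isi
        bins = np.floor((ts - st[a]) / denom * n_bins).astype(np.intp)
        if mode == "interpolated":
            np.clip(bins, 0, n_bins - 1, out=bins)
            keep = slice(None)
        else:
            keep = bins < n_bins
            bins = bins[keep]
        Q[a] = np.bincount(
            bins, weights=current.samples[lo[a] : hi[a]][keep] * dt,
            minlength=n_bins,
        )
    return ChargeMatrix(Q, isis / mean_isi, mode, mean_isi)


class PhaseResettingRegression:
    """OLS model for the infinitesimal PRC given a charge matrix.

    Build directly from a :class:`ChargeMatrix`, or from a current trace
    and spike train with :meth:`from_traces`.
    """

    def __init__(self, charge: ChargeMatrix):
        self.charge = charge
        n_obs, n_bins = charge.Q.shape
        if n_obs < n_bins + 2:
            raise ValueError(
                f"too few intervals ({n_obs}) for {n_bins} bins (+ intercept)"
            )
        if n_obs < n_bins + MIN_EXTRA_INTERVALS:
            raise ValueError(
                f"need at least n_bins + {MIN_EXTRA_INTERVALS} = "
                f"{n_bins + MIN_EXTRA_INTERVALS} intervals, got {n_obs}"
            )
        X = sm.add_constant(charge.Q, has_constant="add")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            zero_cols = np.flatnonzero(np.ptp(charge.Q, axis=0) == 0)
            raise ValueError(
                "charge matrix is rank deficient"
                + (f"; constant columns (0-based bins): {zero_cols.tolist()}"
                   if zero_cols.size else "")
            )
        self._X = X

    @classmethod
    def from_traces(
        cls,
        current: Trace,
        spikes: SpikeTrain,
        n_bins: int | str = "auto",
        mode: str = "interpolated",
        pulse_ms: float | None = None,
    ) -> "PhaseResettingRegression":
        """Bin the current into per-phase charges and set up the model.

        ``n_bins='auto'`` applies the one-pulse-per-bin rule and needs
        ``pulse_ms`` (the noise pulse duration).
        """
        if n_bins == "auto":
            if pulse_ms is None:
                raise ValueError("n_bins='auto' requires pulse_ms")
            mean_isi = float(np.mean(np.diff(spikes.spike_times)))
            n_bins = choose_n_bins(mean_isi, pulse_ms)
        return cls(bin_charges(current, spikes, int(n_bins), mode))

    def fit(self) -> "PhaseResettingResults":
        res = sm.OLS(self.charge.y, self._X).fit()
        return PhaseResettingResults(self, res)


class PhaseResettingResults:
    """Fitted PRC with classical OLS uncertainties.

    ``params`` are the PRC values (negated slope coefficients), ``bse``
    their standard errors sqrt(s^2 * diag((X'X)^-1)), ``rsquared`` the
    share of ISI variance accounted for by the injected noise.
    """

    def __init__(self, model: PhaseResettingRegression, ols_results):
        self.model = model
        self._ols = ols_results
        self.params = -np.asarray(ols_results.params[1:])
        self.bse = np.asarray(ols_results.bse[1:])
        self.intercept = float(ols_results.params[0])
        self.rsquared = float(ols_results.rsquared)
        self.nobs = int(ols_results.nobs)

    @property
    def n_bins(self) -> int:
        return self.params.size

    @property
    def prc(self) -> TabulatedPRC:
        return TabulatedPRC(
            self.model.charge.bin_centers, self.params, self.bse, self.rsquared
        )

    def sensitivity(self) -> float:
        """Integral of the squared fitted PRC (cycles^2/(pA^2*ms^2))."""
        return sensitivity(self.prc)

    def centroid(self) -> float:
        return centroid(self.prc)

    def predicted_cv(self, sigma: float, d: float, omega: float) -> float:
        """Closed-form ISI CV under pulsed noise (sigma pA, d ms) at rate
        omega (spikes/ms), using this fit's sensitivity."""
        from .cvtheory import predicted_cv

        return predicted_cv(sigma, d, omega, self.sensitivity())

    def predict(self, current: Trace, actual: SpikeTrain, omega=None, dt=0.05):
        """Predict the spike times of another episode from this PRC."""
        from .predict import predict_spike_times

        return predict_spike_times(self.prc, omega, current, actual, dt=dt)

    def summary(self) -> str:
        charge = self.model.charge
        lines = [
            "Phase-resetting noise regression",
            "=" * 56,
            f"binning mode       {charge.binning_mode}",
            f"intervals          {self.nobs}",
            f"phase bins         {self.n_bins}",
            f"mean ISI (ms)      {charge.mean_isi:.4g}",
            f"R-squared          {self.rsquared:.4f}",
            f"intercept          {self.intercept:.4f}",
            f"sensitivity        {self.sensitivity():.4g} cycles^2/(pA^2 ms^2)",
            f"centroid (phase)   {self.centroid():.4f}",
            "-" * 56,
            f"{'phase':>8} {'Z [cycles/(pA ms)]':>20} {'SE':>12}",
        ]
        for c, z, se in zip(charge.bin_centers, self.params, self.bse):
            lines.append(f"{c:8.4f} {z:20.6g} {se:12.3g}")
        return "\n".join(lines)


def fit_prc(charge: ChargeMatrix) -> PhaseResettingResults:
    """Convenience: fit the PRC regression on a prepared charge matrix."""
    return PhaseResettingRegression(charge).fit()
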