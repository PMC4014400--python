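"""Spike-time prediction from a measured PRC, and spike-train statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .io import SpikeTrain, Trace
from .prc import TabulatedPRC

__all__ = [
    "PredictionReport",
    "Autocorrelogram",
    "predict_spike_times",
    "variance_explained",
    "isi_cv",
    "autocorrelogram",
    "mean_rate",
]


@dataclass(frozen=True)
class PredictionReport:
    """Per-interval predicted vs. actual ISIs and the variance explained.

    ``predicted_isis`` holds NaN for intervals where the phase never
    crossed 1 within five mean periods (``n_unpredicted`` counts them);
    ``variance_explained`` is computed over the predicted pairs.
    """

    predicted_isis: np.ndarray
    actual_isis: np.ndarray
    variance_explained: float
    dt_used: float
    omega_used: float
    n_unpredicted: int = 0


@dataclass(frozen=True)
class Autocorrelogram:
    """One-sided histogram of pairwise spike-time differences."""

    bin_edges: np.ndarray  # ms
    counts: np.ndarray
    normalization: str = "counts"


def predict_spike_times(
    prc: TabulatedPRC,
    omega: float | None,
    current: Trace,
    actual: SpikeTrain,
    dt: float = 0.05,
    max_periods: float = 5.0,
) -> PredictionReport:
    """Predict each interspike interval of ``actual`` from the PRC.

    The phase model is restarted at every actual spike: phi is integrated
    from 0 under the recorded current (held constant within each recorded
    sample) on a ``dt`` grid, with linear sub-step refinement of the
    phi = 1 crossing; the crossing time is the predicted next spike.
    ``omega`` defaults to the reciprocal of the episode's mean ISI.
    """
    st = actual.spike_times
    if st.size < 2:
        raise ValueError("need at least 2 actual spikes")
    actual_isis = np.diff(st)
    if omega is None:
        omega = 1.0 / float(np.mean(actual_isis))
    if omega <= 0:
        raise ValueError("omega must be positive")
    span = (current.t0, current.t0 + current.duration)
    if st[0] < span[0] - 1e-9 or st[-1] > span[1] + 1e-9:
        raise ValueError("current trace does not cover all intervals")
    predicted = _kernels.predict_isis(
        prc.knots, prc.knot_values, omega, current.samples, current.t0,
        current.dt, st[:-1], dt, max_periods,
    )
    ok = ~np.isnan(predicted)
    try:
        ve = variance_explained(predicted[ok], actual_isis[ok])
    except ValueError:  # too few predicted pairs or perfectly periodic data
        ve = float("nan")
    return PredictionReport(
        predicted, actual_isis, ve, dt, float(omega), int((~ok).sum())
    )


def variance_explained(predicted, actual, method: str = "ss") -> float:
    """Fraction of ISI variance accounted for by the prediction.

    ``method='ss'`` (default): 1 - SS_res/SS_tot with SS_tot about the mean
    actual ISI — penalises bias and can be negative for bad predictions.
    ``method='corr'``: squared Pearson correlation.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    if predicted.size < 3:
        raise ValueError("need at least 3 interval pairs")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("actual intervals have zero variance")
    if method == "ss":
        return 1.0 - float(np.sum((actual - predicted) ** 2)) / ss_tot
    if method == "corr":
        r = np.corrcoef(predicted, actual)[0, 1]
        return float(r * r)
    raise ValueError("method must be 'ss' or 'corr'")


def isi_cv(spikes: SpikeTrain | np.ndarray) -> float:
    """SD(ISI)/mean(ISI) with the n-1 denominator; needs >= 3 intervals."""
    isis = spikes.isis() if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    if isis.size < 3:
        raise ValueError("need at least 3 interspike intervals")
    return float(np.std(isis, ddof=1) / np.mean(isis))


def autocorrelogram(
    spikes: SpikeTrain,
    binwidth: float,
    max_lag: float,
    normalization: str = "counts",
) -> Autocorrelogram:
    """Histogram of all positive pairwise spike-time differences <= max_lag.

    Zero-lag self pairs are excluded.  ``normalization='rate'`` divides the
    counts by n_spikes * binwidth(s), giving a conditional rate in spikes/s.
    """
    if binwidth <= 0 or max_lag < binwidth:
        raise ValueError("need binwidth > 0 and max_lag >= binwidth")
    if normalization not in ("counts", "rate"):
        raise ValueError("normalization must be 'counts' or 'rate'")
    st = spikes.spike_times
    edges = np.arange(0.0, max_lag + binwidth, binwidth)
    edges = edges[edges <= max_lag + 1e-12]
    counts = np.zeros(edges.size - 1)
    if st.size >= 2:
        hi = np.searchsorted(st, st + max_lag, side="right")
        diffs = [st[k + 1 : hi[k]] - st[k] for k in range(st.size - 1)]
        if diffs:
            lags = np.concatenate(diffs)
            counts, _ = np.histogram(lags, bins=edges)
    counts = counts.astype(float)
    if normalization == "rate" and st.size:
        counts /= st.size * (binwidth / 1000.0)
    return Autocorrelogram(edges, counts, normalization)


def mean_rate(spikes: SpikeTrain) -> float:
    """Mean firing rate in spikes/s: (n-1)/(last - first), times 1000."""
    st = spikes.spike_times
    if st.size < 2:
        raise ValueError("need at least 2 spikes")
    return 1000.0 * (st.size - 1) / float(st[-1] - st[0])
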