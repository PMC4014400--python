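"""Trace and spike-train containers, delimited-text I/O, spike detection,
and the pulse-slope recording-quality check.

Package-wide units: time in ms, current in pA, voltage in mV, charge in
pA*ms, phase in cycles (0 to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Trace",
    "SpikeTrain",
    "QCReport",
    "read_trace",
    "write_trace",
    "read_spike_train",
    "write_spike_train",
    "detect_spikes",
    "pulse_slope_qc",
]

#: relative tolerance on time-step uniformity when reading two-column files
_DT_RTOL = 1e-6


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled time series (current in pA or voltage in mV)."""

    t0: float
    dt: float
    samples: np.ndarray
    kind: str = "current"  # {"current", "voltage"}

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-d array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("all samples must be finite")
        if self.kind not in ("current", "voltage"):
            raise ValueError("kind must be 'current' or 'voltage'")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Start time of every sample."""
        return self.t0 + self.dt * np.arange(self.n)

    def value_at(self, t: float) -> float:
        """Sample covering time ``t`` (samples are held constant for dt)."""
        idx = int(np.floor((t - self.t0) / self.dt))
        idx = min(max(idx, 0), self.n - 1)
        return float(self.samples[idx])


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) within a recording span."""

    spike_times: np.ndarray
    span: tuple[float, float]

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike_times must be 1-d")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        lo, hi = self.span
        if hi <= lo:
            raise ValueError("span must have positive length")
        if times.size and (times[0] < lo or times[-1] > hi):
            raise ValueError("spike times must lie within span")
        object.__setattr__(self, "spike_times", times)
        object.__setattr__(self, "span", (float(lo), float(hi)))

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class QCReport:
    """Per-pulse voltage slopes vs. pulse amplitude, and their linearity.

    For brief current pulses into a well-compensated recording the membrane
    response is primarily capacitative, so each pulse produces a voltage
    ramp whose slope is proportional to the pulse amplitude (slope = I/C
    for an ideal capacitor).  ``linearity_slope`` is the fitted
    (mV/ms)/pA coefficient and ``linearity_r2`` the R^2 of that fit;
    thresholds for "acceptable" are left to the user.
    """

    per_pulse_slope: np.ndarray  # mV/ms
    per_pulse_amplitude: np.ndarray  # pA
    linearity_slope: float  # (mV/ms)/pA
    linearity_r2: float

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"linearity_slope\t{self.linearity_slope:.10g}\n")
            fh.write(f"linearity_r2\t{self.linearity_r2:.10g}\n")
            fh.write(f"n_pulses\t{self.per_pulse_slope.size}\n")


# ---------------------------------------------------------------------------
# delimited-text trace I/O
#
# Two dialects, comma- or tab-delimited, '#'-prefixed header lines:
#   two-column:     time_ms, value per row; dt inferred (must be uniform)
#   single-column:  one value per row; header must declare "# dt_ms=..."
#                   and may declare "# t0_ms=..." and "# kind=..."


def _split(line: str) -> list[str]:
    return line.replace(",", " ").replace("\t", " ").split()


def read_trace(path, kind: str | None = None) -> Trace:
    """Read a trace from delimited text (two-column or single-column dialect)."""
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for part in line[1:].replace(",", " ").split():
                    if "=" in part:
                        k, v = part.split("=", 1)
                        header[k.strip()] = v.strip()
                continue
            fields = _split(line)
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric row {lineno}: {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: empty trace file")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError(f"{path}: inconsistent column count")
    kind = kind or header.get("kind", "current")
    if ncol == 1:
        if "dt_ms" not in header:
            raise ValueError(f"{path}: single-column dialect requires '# dt_ms=' header")
        dt = float(header["dt_ms"])
        t0 = float(header.get("t0_ms", 0.0))
        return Trace(t0, dt, np.array([r[0] for r in rows]), kind)
    if ncol == 2:
        arr = np.asarray(rows, dtype=float)
        t, v = arr[:, 0], arr[:, 1]
        if t.size < 2:
            return Trace(float(t[0]), float(header.get("dt_ms", 1.0)), v, kind)
        steps = np.diff(t)
        dt = float(np.median(steps))
        dev = np.abs(steps - dt)
        tol = max(_DT_RTOL * dt, 1e-12)
        if np.any(dev > tol):
            i = int(np.argmax(dev))
            raise ValueError(
                f"{path}: non-uniform sampling at row {i + 2} "
                f"(step {steps[i]:.9g} vs dt {dt:.9g}, max deviation {dev[i]:.3g})"
            )
        return Trace(float(t[0]), dt, v, kind)
    raise ValueError(f"{path}: expected 1 or 2 columns, found {ncol}")


def write_trace(trace: Trace, path, dialect: str = "single-column") -> None:
    """Write a trace as delimited text; round-trips to full precision."""
    with open(path, "w") as fh:
        if dialect == "single-column":
            fh.write(f"# dt_ms={float(trace.dt)!r} t0_ms={float(trace.t0)!r} kind={trace.kind}\n")
            for v in trace.samples:
                fh.write(f"{float(v)!r}\n")
        elif dialect == "two-column":
            fh.write(f"# kind={trace.kind}\n")
            for i, v in enumerate(trace.samples):
                fh.write(f"{float(trace.t0 + i * trace.dt)!r}\t{float(v)!r}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_spike_train(path) -> SpikeTrain:
    """Read spike times, one per line; '# span=a,b' header optional."""
    span = None
    times = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "span=" in line:
                    a, b = line.split("span=")[1].split(",")
                    span = (float(a), float(b))
                continue
            times.append(float(line))
    times = np.asarray(times, dtype=float)
    if span is None:
        span = (float(times[0]), float(times[-1])) if times.size else (0.0, 1.0)
    return SpikeTrain(times, span)


def write_spike_train(train: SpikeTrain, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# span={float(train.span[0])!r},{float(train.span[1])!r}\n")
        for t in train.spike_times:
            fh.write(f"{float(t)!r}\n")


# ---------------------------------------------------------------------------


def detect_spikes(v: Trace, threshold: float, refractory: float) -> SpikeTrain:
    """Detect spikes as upward threshold crossings of a voltage trace.

    The spike time is the time of the first sample at/above ``threshold``
    in each upward crossing; further crossings within ``refractory`` ms are
    suppressed.  Invariant to adding a common offset to trace and threshold.
    """
    if v.kind != "voltage":
        raise ValueError("detect_spikes requires a voltage trace")
    if refractory < v.dt:
        raise ValueError("refractory must be >= dt")
    if threshold <= float(np.min(v.samples)) and v.n > 1:
        raise ValueError("threshold at/below trace minimum: would fire everywhere")
    above = v.samples >= threshold
    onsets = np.flatnonzero(above & ~np.concatenate(([True], above[:-1])))
    if above[0]:
        onsets = np.concatenate(([0], onsets))
    spike_times = []
    last = -np.inf
    for idx in onsets:
        t = v.t0 + idx * v.dt
        if t - last >= refractory:
            spike_times.append(t)
            last = t
    return SpikeTrain(np.asarray(spike_times), (v.t0, v.t0 + v.duration))


def pulse_slope_qc(v: Trace, i: Trace, d: float) -> QCReport:
    """Check that voltage-ramp slopes scale linearly with pulse amplitude.

    Splits both traces into contiguous pulses of duration ``d``, fits a
    least-squares slope to the voltage within each pulse (excluding the
    first sample, which carries the capacitative switching transient), and
    regresses those slopes on the pulse amplitudes.
    """
    if abs(v.dt - i.dt) > 1e-12 or v.n != i.n or abs(v.t0 - i.t0) > 1e-9:
        raise ValueError("voltage and current traces must share dt, t0 and length")
    n_per = d / v.dt
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("pulse duration must be a multiple of dt")
    n_per = int(round(n_per))
    if n_per < 3:
        raise ValueError("need at least 3 samples per pulse to fit a slope")
    n_pulses = v.n // n_per
    if n_pulses < 3:
        raise ValueError("need at least 3 complete pulses")
    slopes = np.empty(n_pulses)
    amps = np.empty(n_pulses)
    # time axis within a pulse, first sample excluded
    tt = v.dt * np.arange(1, n_per)
    tt = tt - tt.mean()
    denom = float(np.sum(tt * tt))
    for k in range(n_pulses):
        seg_v = v.samples[k * n_per + 1 : (k + 1) * n_per]
        slopes[k] = float(np.sum(tt * (seg_v - seg_v.mean()))) / denom
        amps[k] = i.samples[k * n_per]
    if np.ptp(amps) == 0.0:
        raise ValueError("all pulse amplitudes identical: linearity regression degenerate")
    a = amps - amps.mean()
    s = slopes - slopes.mean()
    beta = float(np.sum(a * s) / np.sum(a * a))
    ss_res = float(np.sum((s - beta * a) ** 2))
    ss_tot = float(np.sum(s * s))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return QCReport(slopes, amps, beta, min(max(r2, 0.0), 1.0))
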