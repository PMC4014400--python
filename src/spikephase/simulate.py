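"""Phase-model simulation: pulsed Gaussian noise, single trajectories, and
Monte Carlo ensembles.

The model: a repetitively firing neuron is reduced to a single phase
variable phi on [0, 1) advancing as

    dphi/dt = omega + Z(phi) * I(t)

where omega is the intrinsic firing rate (spikes/ms), Z the infinitesimal
PRC and I the injected current.  Integration is explicit first order on a
fixed grid; a spike occurs when phi crosses 1.  Two conventions follow the
crossing: *restart* (phi resets, producing an ongoing spike train) and
*drift-after-crossing* (input is discontinued and phi drifts on at omega,
which maps phases > 1 onto time since the spike and lets a whole ensemble
be sliced at any time).

Noise is a sequence of contiguous constant current pulses of fixed duration
d whose amplitudes are i.i.d. zero-mean Gaussian with SD sigma — the
discrete-time, finite-bandwidth stand-in for white current noise that an
electrophysiology rig can actually deliver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import _kernels
from .io import SpikeTrain, Trace
from .prc import TabulatedPRC

__all__ = [
    "NoiseSpec",
    "SimConfig",
    "PhaseEnsemble",
    "TrajectoryResult",
    "generate_pulsed_noise",
    "simulate_trajectory",
    "simulate_ensemble",
    "phase_distribution_at",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Pulsed Gaussian noise: duration d (ms), amplitude SD sigma (pA), seed."""

    d: float
    sigma: float
    seed: int = 0

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("pulse duration d must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo ensemble configuration.

    Defaults mirror the desk-scale Monte Carlo conditions: 1000 ms period
    (omega = 0.001 spikes/ms), 1 ms step, 5000 trajectories,
    drift-after-crossing convention.
    """

    omega: float = 0.001
    dt: float = 1.0
    n_traj: int = 5000
    mode: str = "drift-after-crossing"

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if self.mode not in ("restart", "drift-after-crossing"):
            raise ValueError("mode must be 'restart' or 'drift-after-crossing'")


class TrajectoryResult(NamedTuple):
    spikes: SpikeTrain
    phases: np.ndarray
    n_clamped: int  # steps on which phi was clamped at 0 from below


@dataclass
class PhaseEnsemble:
    """Latent-phase trajectories with per-trajectory first-crossing times.

    ``phases`` is (n_traj, n_times) in float32; the integration itself runs
    in float64 and crossing times are taken from the float64 state.
    """

    times: np.ndarray
    phases: np.ndarray
    crossing_times: np.ndarray
    omega: float
    n_clamped: int = 0

    @property
    def n_traj(self) -> int:
        return self.phases.shape[0]

    def isi_mean(self) -> float:
        return float(np.mean(self.crossing_times))

    def isi_variance(self) -> float:
        return float(np.var(self.crossing_times, ddof=1))

    def isi_cv(self) -> float:
        return float(np.std(self.crossing_times, ddof=1) / np.mean(self.crossing_times))


def generate_pulsed_noise(
    spec: NoiseSpec,
    duration: float,
    dt: float,
    rng: np.random.Generator | None = None,
    t0: float = 0.0,
) -> Trace:
    """Contiguous constant pulses of duration ``spec.d`` with i.i.d.
    N(0, sigma^2) amplitudes, sampled at ``dt``.  Reproducible from
    ``spec.seed`` when no generator is passed."""
    spp = spec.d / dt
    if abs(spp - round(spp)) > 1e-9:
        raise ValueError("pulse duration d must be an integer multiple of dt")
    spp = int(round(spp))
    n_pulses = duration / spec.d
    if abs(n_pulses - round(n_pulses)) > 1e-9:
        raise ValueError("duration must be an integer multiple of d")
    n_pulses = int(round(n_pulses))
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    amps = rng.normal(0.0, spec.sigma, n_pulses)
    return Trace(t0, dt, np.repeat(amps, spp), "current")


def simulate_trajectory(
    prc: TabulatedPRC,
    omega: float,
    current: Trace,
    dt: float | None = None,
    mode: str = "restart",
    refine: bool = False,
) -> TrajectoryResult:
    """Integrate one phase trajectory driven by a recorded current.

    ``dt`` defaults to the current's sample interval; the current sample
    covering each step is held constant.  ``refine`` places spike times at
    the linear sub-step crossing of phi = 1 (and carries the overshoot into
    the next cycle in restart mode), making the zero-noise ISI exactly
    1/omega; without it spikes land on the first grid time with phi >= 1.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if mode not in ("restart", "drift-after-crossing"):
        raise ValueError("mode must be 'restart' or 'drift-after-crossing'")
    if dt is None:
        dt = current.dt
    n_steps = int(round(current.duration / dt))
    max_spikes = int(current.duration * omega * 10) + 16
    spikes, phases, clamps = _kernels.euler_trajectory(
        prc.knots, prc.knot_values, omega, current.samples, current.t0,
        current.dt, current.t0, dt, n_steps, mode == "restart", refine,
        max_spikes,
    )
    train = SpikeTrain(spikes, (current.t0, current.t0 + current.duration))
    return TrajectoryResult(train, phases, int(clamps))


def simulate_ensemble(
    prc: TabulatedPRC,
    omega: float | None = None,
    noise: NoiseSpec | None = None,
    config: SimConfig | None = None,
) -> PhaseEnsemble:
    """Monte Carlo ensemble of drift-after-crossing trajectories.

    Each trajectory gets an independent noise stream seeded from
    (noise.seed, trajectory index), so results do not depend on execution
    order.  The simulation runs until every trajectory has crossed phi = 1
    (and at least a little past the mean period), so the ensemble can be
    sliced at any time in the first interspike interval.
    """
    config = config or SimConfig()
    if omega is None:
        omega = config.omega
    if noise is None:
        raise ValueError("a NoiseSpec is required")
    if config.n_traj < 2:
        raise ValueError("ensembles need n_traj >= 2")
    dt = config.dt
    spp = noise.d / dt
    if abs(spp - round(spp)) > 1e-9:
        raise ValueError("pulse duration d must be an integer multiple of dt")
    spp = int(round(spp))
    n = config.n_traj
    gens = [
        np.random.default_rng(np.random.SeedSequence((noise.seed, i)))
        for i in range(n)
    ]
    knots, kvals = prc.knots, prc.knot_values

    phi = np.zeros(n)
    crossing = np.full(n, np.nan)
    snapshots = [phi.astype(np.float32)]
    clamps = 0
    # grow in chunks of one mean period until everyone has crossed
    chunk_pulses = max(int(round(1.0 / (omega * noise.d))), 1)
    chunk_steps = chunk_pulses * spp
    t_min = 1.05 / omega
    t_cap = 20.0 / omega
    k_global = 0
    while True:
        amps = np.empty((n, chunk_pulses))
        for i, g in enumerate(gens):
            amps[i] = g.normal(0.0, noise.sigma, chunk_pulses)
        for j in range(chunk_steps):
            amp = amps[:, j // spp]
            z = np.interp(phi, knots, kvals)  # 0 past phase 1: noise off
            phi = phi + dt * (omega + z * amp)
            neg = phi < 0.0
            if np.any(neg):
                clamps += int(neg.sum())
                phi[neg] = 0.0
            k_global += 1
            newly = (phi >= 1.0) & np.isnan(crossing)
            if np.any(newly):
                crossing[newly] = k_global * dt
            snapshots.append(phi.astype(np.float32))
        t_now = k_global * dt
        if (not np.any(np.isnan(crossing)) and t_now >= t_min) or t_now >= t_cap:
            break
    if np.any(np.isnan(crossing)):
        raise RuntimeError("some trajectories never crossed phase 1 within 20 periods")
    times = dt * np.arange(len(snapshots))
    return PhaseEnsemble(times, np.stack(snapshots, axis=1), crossing, omega, clamps)


def phase_distribution_at(
    ensemble: PhaseEnsemble, t: float, n_hist_bins: int = 50
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Mean, sample variance and histogram of latent phase at the stored
    sample nearest ``t`` (a vertical slice through the trajectories)."""
    if t < 0 or t > ensemble.times[-1]:
        raise ValueError("t outside the simulated horizon")
    idx = int(np.argmin(np.abs(ensemble.times - t)))
    phases = ensemble.phases[:, idx].astype(float)
    mean = float(np.mean(phases))
    var = float(np.var(phases, ddof=1)) if phases.size > 1 else 0.0
    hist = np.histogram(phases, bins=n_hist_bins)
    return mean, var, hist
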