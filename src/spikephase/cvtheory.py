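"""Closed-form prediction of spike-time variability from the PRC.

For a phase oscillator at rate omega (spikes/ms) perturbed by contiguous
zero-mean Gaussian current pulses (duration d ms, amplitude SD sigma pA),
each pulse delivers charge with variance d^2 sigma^2 and there are
1/(d*omega) pulses per mean interval, so squared charge accumulates at rate
d sigma^2 / omega per interval.  Under the small-noise approximation the
phase variance grows with the local squared PRC, giving at the mean firing
time Var(phase) = d sigma^2 S / omega with S = integral of Z^2 (the
sensitivity); ISI variance is that scaled by 1/omega^2, hence

    CV = sigma * sqrt(d * S / omega)

— linear in sigma, proportional to sqrt(d) and to 1/sqrt(omega).  The
approximation assumes the phase distribution stays narrow; it degrades as
the Monte Carlo CV grows large.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .prc import TabulatedPRC

__all__ = ["predicted_cv", "phase_variance_evolution", "cv_curve"]


def predicted_cv(sigma: float, d: float, omega: float, sensitivity: float) -> float:
    """Closed-form ISI coefficient of variation, sigma*sqrt(d*S/omega)."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    if sigma < 0 or d < 0 or sensitivity < 0:
        raise ValueError("sigma, d and sensitivity must be nonnegative")
    return float(sigma * np.sqrt(d * sensitivity / omega))


def _running_sq_integral(prc: TabulatedPRC, u) -> np.ndarray:
    """Exact running integral of Z^2 along phase for the piecewise-linear
    interpolant: int_0^u Z(x)^2 dx, vectorised over u in [0, 1]."""
    x = prc.knots
    z = prc.knot_values
    h = np.diff(x)
    a, b = z[:-1], z[1:]
    seg = h * (a * a + a * b + b * b) / 3.0
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    j = np.clip(np.searchsorted(x, u, side="right") - 1, 0, h.size - 1)
    w = u - x[j]
    m = (b - a)[j] / h[j]
    aj = a[j]
    partial = aj * aj * w + aj * m * w * w + m * m * w**3 / 3.0
    return cum[j] + partial


def phase_variance_evolution(
    prc: TabulatedPRC, omega: float, sigma: float, d: float, t
) -> np.ndarray | float:
    """Approximate variance of the latent-phase distribution at time t.

    Var(t) = (d sigma^2 / omega) * int_0^{omega t} Z(u)^2 du — the running
    integral of the squared PRC along the mean phase trajectory.  At
    t = 1/omega this equals d sigma^2 S / omega = predicted_cv(...)**2;
    dividing by omega^2 converts it to the predicted ISI variance.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = (d * sigma**2 / omega) * _running_sq_integral(prc, omega * t_arr)
    return out if out.ndim else float(out)


def cv_curve(
    prc: TabulatedPRC,
    omega: float,
    d: float,
    sigma_grid,
    monte_carlo: bool = False,
    n_traj: int = 5000,
    dt: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted CV over a grid of noise SDs; optionally paired with a
    Monte Carlo ensemble estimate per grid point (column ``cv_mc``)."""
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_grid.size == 0:
        raise ValueError("sigma grid must be nonempty")
    s = prc.sensitivity()
    cv = np.array([predicted_cv(sig, d, omega, s) for sig in sigma_grid])
    table = pd.DataFrame({"sigma": sigma_grid, "cv": cv})
    if monte_carlo:
        from .simulate import NoiseSpec, SimConfig, simulate_ensemble

        mc = np.empty_like(sigma_grid)
        for k, sig in enumerate(sigma_grid):
            ens = simulate_ensemble(
                prc,
                noise=NoiseSpec(d, sig, seed + k),
                config=SimConfig(omega=omega, dt=dt, n_traj=n_traj),
            )
            mc[k] = ens.isi_cv()
        table["cv_mc"] = mc
    return table
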