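"""Compiled inner loops for the sequential Euler integrations.

The phase update is inherently sequential in time, so the long
single-trajectory runs (restart-mode spike-train generation, per-interval
spike-time prediction on a 0.05 ms grid) are jitted with numba.  Ensemble
simulation is vectorised over trajectories in plain NumPy and lives in
:mod:`spikephase.simulate`.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def euler_trajectory(knots, kvals, omega, cur, cur_t0, cur_dt, t0, dt,
                     n_steps, restart, refine, max_spikes):
    """First-order phase-model integration over a recorded current.

    phi <- phi + dt * (omega + Z(phi) * I(t)); a spike is recorded when phi
    crosses 1.  ``restart`` resets phi at each crossing (carrying the
    sub-step overshoot when ``refine``); otherwise a single crossing is
    recorded and the trajectory drifts on at omega with input discontinued.
    Returns (spike_times, phases, n_clamped).
    """
    phi = 0.0
    phases = np.empty(n_steps + 1)
    phases[0] = 0.0
    spikes = np.empty(max_spikes)
    ns = 0
    clamps = 0
    crossed = False
    ncur = cur.size
    for k in range(n_steps):
        t = t0 + k * dt
        idx = int((t - cur_t0) / cur_dt)
        if idx < 0:
            idx = 0
        elif idx >= ncur:
            idx = ncur - 1
        amp = cur[idx]
        if crossed and not restart:
            amp = 0.0
        z = np.interp(phi, knots, kvals)
        new = phi + dt * (omega + z * amp)
        if new < 0.0:
            new = 0.0
            clamps += 1
        if new >= 1.0 and (restart or not crossed):
            if ns < max_spikes:
                if refine:
                    spikes[ns] = t + dt * (1.0 - phi) / (new - phi)
                else:
                    spikes[ns] = t + dt
                ns += 1
            if restart:
                new = new - 1.0 if refine else 0.0
                if new >= 1.0:
                    new = 0.0  # pathological overshoot of a full cycle
            else:
                crossed = True
        phases[k + 1] = new
        phi = new
    return spikes[:ns], phases, clamps


@njit(cache=True)
def predict_isis(knots, kvals, omega, cur, cur_t0, cur_dt, starts, dt,
                 max_periods):
    """Predicted ISI for each actual spike: integrate phi from 0 at the
    spike under the recorded current until phi crosses 1 (with linear
    sub-step crossing refinement).  NaN if no crossing within
    ``max_periods`` mean periods."""
    n = starts.size
    out = np.empty(n)
    ncur = cur.size
    n_max = int(max_periods / (omega * dt)) + 1
    for a in range(n):
        s = starts[a]
        phi = 0.0
        pred = np.nan
        for j in range(n_max):
            t = s + j * dt
            idx = int((t - cur_t0) / cur_dt)
            if idx < 0:
                idx = 0
            elif idx >= ncur:
                idx = ncur - 1
            z = np.interp(phi, knots, kvals)
            new = phi + dt * (omega + z * cur[idx])
            if new < 0.0:
                new = 0.0
            if new >= 1.0:
                pred = t + dt * (1.0 - phi) / (new - phi) - s
                break
            phi = new
        out[a] = pred
    return out
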