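import numpy as np
import pytest

import spikephase as sp


@pytest.fixture(scope="session")
def mc_prc():
    """Raised-cosine PRC at Monte Carlo scale: at 1 spike/s the 25-800 pA
    pulse-amplitude range spans ISI CVs up to ~0.5."""
    return sp.raised_cosine_prc(sensitivity_target=4e-10)


@pytest.fixture(scope="session")
def noisy_run(mc_prc):
    """A long restart-mode run at 1 spike/s with moderate pulsed noise
    (~1200 ISIs), shared by the regression tests."""
    cur = sp.generate_pulsed_noise(sp.NoiseSpec(1.0, 300.0, seed=42), 1_200_000.0, 1.0)
    res = sp.simulate_trajectory(mc_prc, 0.001, cur, 1.0, "restart", refine=True)
    return cur, res.spikes


@pytest.fixture(scope="session")
def stn_experiment():
    """Default synthetic recording: 10 spikes/s, STN-scale sensitivity,
    60 pA / 0.5 ms injected noise, hidden intrinsic noise at 80% share."""
    return sp.synth_experiment(seed=0)
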