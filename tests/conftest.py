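"""Shared fixtures: small synthetic traces with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from okndecode.simulate import (
    GazeTrace,
    LatentPerceptTrace,
    OknParams,
    PerceptProcessParams,
    simulate_okn,
)


@pytest.fixture(scope="session")
def clean_okn_params() -> OknParams:
    """Noise- and blink-free OKN parameters for deterministic checks."""
    return OknParams(noise_sd=0.0, blink_rate=0.0)


@pytest.fixture(scope="session")
def sawtooth_trace(clean_okn_params) -> GazeTrace:
    """60-s noise-free sawtooth driven by a 2-state latent trace."""
    states = np.zeros(60 * 100, dtype=np.int8)
    states[30 * 100:] = 1  # integrated first half, segregated second
    latent = LatentPerceptTrace(rate=100.0, states=states)
    return simulate_okn(latent, clean_okn_params, rate=1000.0, seed=7)


@pytest.fixture(scope="session")
def noisy_trace() -> GazeTrace:
    """60-s sawtooth with default noise and blinks."""
    rng = np.random.default_rng(11)
    states = (rng.random(60 * 100) < 0.5).astype(np.int8)
    # smooth into ~6-s phases
    states = np.repeat((rng.random(10) < 0.5).astype(np.int8), 600)
    latent = LatentPerceptTrace(rate=100.0, states=states)
    return simulate_okn(latent, OknParams(), rate=1000.0, seed=12)


@pytest.fixture(scope="session")
def ramp_trace() -> GazeTrace:
    """Pure 2-deg/s linear ramp, 10 s."""
    t = np.arange(10_000) / 1000.0
    return GazeTrace(t=t, x=2.0 * t, valid=np.ones(10_000, dtype=bool))


@pytest.fixture
def default_percept_params() -> PerceptProcessParams:
    return PerceptProcessParams()
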