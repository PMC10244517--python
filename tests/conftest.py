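"""Shared fixtures: small noise-free phantoms and deterministic RNGs.

Everything is generated programmatically at test time; grids are kept at
desk scale so the whole suite runs on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from dixonmuscle.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 6-muscle phantom with the designed FF ladder
    {5, 20, 40, 60, 80, 95}%% on the default 96x96x48 grid."""
    cfg = PhantomConfig(noise_sigma=0.0)
    dixon, truth = generate_phantom(cfg)
    return cfg, dixon, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry with the default 2%% Gaussian channel noise."""
    cfg = PhantomConfig(noise_sigma=0.02, seed=7)
    dixon, truth = generate_phantom(cfg)
    return cfg, dixon, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
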