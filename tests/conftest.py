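"""Shared fixtures: small generator configs and seeded RNG streams."""

import numpy as np
import pytest

from adstdp.config import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A fast 10 s / 32-afferent configuration for generator unit tests."""
    return GeneratorConfig(n_aff=32, n_active=32, duration=10.0,
                           appearance_rate=0.25, seed=7)


@pytest.fixture
def tiny_cfg():
    """A 5 s / 16-afferent configuration for the cheapest checks."""
    return GeneratorConfig(n_aff=16, n_active=8, duration=5.0,
                           appearance_rate=0.2, seed=3)
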