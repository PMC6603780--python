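"""Shared fixtures: synthetic scenes reused across test modules."""

import numpy as np
import pytest

from radarvitals.filtering import extract_bands
from radarvitals.reconstruction import reconstruct
from radarvitals.simulator import (
    ChannelConfig,
    VitalMotionConfig,
    make_scene,
    synth_displacement,
    synth_quadrature,
)


@pytest.fixture(scope="session")
def default_scene():
    """One 30 s scene with realistic distortions, reconstructed once."""
    motion = VitalMotionConfig(duration_s=30.0, heart_rate=60.0, heart_rate_jitter=0.02)
    channel = ChannelConfig(iq_offset=0.25 - 0.15j, iq_gain_ratio=1.3, iq_rotation=0.4)
    return make_scene(motion, channel, seed=42)


@pytest.fixture(scope="session")
def default_reconstruction(default_scene):
    return reconstruct(default_scene.quadrature)


@pytest.fixture(scope="session")
def default_bands(default_reconstruction):
    return extract_bands(default_reconstruction)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
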