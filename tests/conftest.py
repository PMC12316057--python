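import numpy as np
import pytest

from afseg.phantom import (
    InterstitiumParams,
    MuscleParams,
    NoiseParams,
    PhantomConfig,
    ScaffoldParams,
    VesselParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """A quick 64x64 two-slice phantom for structural tests."""
    return PhantomConfig(width=64, height=64, n_slices=2, seed=7)


@pytest.fixture
def clean_config():
    """Noise-free, attenuation-free phantom: geometry tests only."""
    return PhantomConfig(
        width=64,
        height=64,
        n_slices=3,
        seed=7,
        noise=NoiseParams(photon_gain=0.0, read_sd=0.0),
        depth_attenuation=1.0,
    )


@pytest.fixture
def flat_config():
    """Degenerate phantom: every texture knob at zero, noise off."""
    return PhantomConfig(
        width=48,
        height=48,
        n_slices=1,
        seed=3,
        muscle=MuscleParams(contrast=0.0),
        scaffold=ScaffoldParams(contrast=0.0),
        interstitium=InterstitiumParams(contrast=0.0, grain=0.0),
        vessel=VesselParams(brightness=1.0, grain=0.0),
        noise=NoiseParams(photon_gain=0.0, read_sd=0.0),
        depth_attenuation=1.0,
    )
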