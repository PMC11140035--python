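import numpy as np
import pytest

from organoidlab import (
    AcquisitionConfig,
    OrganoidPhantom,
    SimSpec,
    extract_harmonic,
    homogeneous_phantom,
    simulate_reverberant_field,
)


@pytest.fixture(scope="session")
def default_acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionConfig:
    """Coarser, shorter acquisition for fast unit tests."""
    return AcquisitionConfig(grid_points=(41, 41), n_timepoints=250)


@pytest.fixture(scope="session")
def two_compartment_phantom() -> OrganoidPhantom:
    """Stiff shell (3 m/s) around a softer core (1.5 m/s), agarose background."""
    return OrganoidPhantom()


@pytest.fixture(scope="session")
def homogeneous_harmonic(default_acq):
    """Harmonic field of a homogeneous vs = 2 m/s reverberant simulation."""
    phantom = homogeneous_phantom(2.0, default_acq)
    v = simulate_reverberant_field(phantom, default_acq, SimSpec(rng_seed=11))
    return extract_harmonic(v)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
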