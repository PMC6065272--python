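import numpy as np
import pytest

from sticklevision.spectra_io import STANDARD_GRID, Spectrum
from sticklevision.synthetic_data import SimConfig, simulate_irradiance, simulate_males


@pytest.fixture(scope="session")
def grid():
    return STANDARD_GRID


@pytest.fixture
def flat_spectrum():
    return Spectrum(STANDARD_GRID, np.ones_like(STANDARD_GRID), "reflectance")


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(
        seed=11,
        noise_sd_reflectance=0.0,
        lamp_drift_sd=0.0,
        irradiance_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_field(noiseless_config):
    return simulate_irradiance(noiseless_config)


@pytest.fixture(scope="session")
def small_study():
    """A 6-male study with defaults scaled down, shared across tests."""
    return simulate_males(SimConfig(n_males=6, seed=5))
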