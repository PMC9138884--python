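import numpy as np
import pytest

from pclar import (DetectorConfig, OpticalContext, SphereParticle,
                   TransitEvent, default_angle_grid, simulate_pclar)


@pytest.fixture(scope="session")
def water_context() -> OpticalContext:
    return OpticalContext(wavelength_nm=532.0, n_medium=1.330)


@pytest.fixture(scope="session")
def silica_particle() -> SphereParticle:
    return SphereParticle(diameter_um=10.0, n_particle=1.451 + 0.003j)


@pytest.fixture(scope="session")
def silica_profile(silica_particle, water_context):
    return simulate_pclar(silica_particle, water_context)


@pytest.fixture(scope="session")
def theta_grid() -> np.ndarray:
    return default_angle_grid()


@pytest.fixture
def default_detector() -> DetectorConfig:
    return DetectorConfig()


def make_transit(profile, arrival_time=0.1, amplitude=20.0, duration=4e-3,
                 label=None):
    return TransitEvent(pclar=profile, arrival_time=arrival_time,
                        peak_amplitude=amplitude, duration=duration,
                        label=label)
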