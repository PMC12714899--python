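import numpy as np
import pytest

from thermopref import ArenaGeometry, ThermalCalibration, zone_center_temperatures


@pytest.fixture(scope="session")
def arena():
    return ArenaGeometry()


@pytest.fixture(scope="session")
def calib():
    return ThermalCalibration.nominal()


@pytest.fixture(scope="session")
def zone_temps(arena, calib):
    return zone_center_temperatures(arena, calib)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
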