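import numpy as np
import pytest

from maim.optics import AngleGrid, AxialGrid, OpticalConfig, build_system_matrix


@pytest.fixture(scope="session")
def config():
    return OpticalConfig()


@pytest.fixture(scope="session")
def angles20():
    """The standard reconstruction grid: 20 angles, 61.5 to 71 deg."""
    return AngleGrid.from_start_step(61.5, 0.5, 20)


@pytest.fixture(scope="session")
def axial():
    return AxialGrid.from_range(600.0, 10.0)


@pytest.fixture(scope="session")
def sysmat(angles20, axial, config):
    return build_system_matrix(angles20, axial, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
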