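import numpy as np
import pytest

from capsnav import (coil_basis, default_ema_config, default_magnet_spec,
                     default_sensor_array)


@pytest.fixture(scope="session")
def spec():
    return default_magnet_spec()


@pytest.fixture(scope="session")
def array():
    return default_sensor_array()


@pytest.fixture(scope="session")
def ema_config():
    return default_ema_config()


@pytest.fixture(scope="session")
def sensor_basis(ema_config, array):
    """Unit-current coil field table at the 36 sensor positions."""
    return coil_basis(ema_config, array.positions)


@pytest.fixture(scope="session")
def zero_basis(array):
    """A ten-coil basis of zeros: frames synthesized against it carry no
    actuation field regardless of the current vector."""
    return np.zeros((10, array.n_sensors, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
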