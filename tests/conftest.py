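import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from socrcc import BerryParams, NetworkConfig, PerturbationSchedule, RCCParams


@pytest.fixture(scope="session")
def bp():
    return BerryParams()


@pytest.fixture(scope="session")
def rcc():
    return RCCParams()


@pytest.fixture
def small_net():
    """A 2x2 four-unit network with hand-set weights (fast to integrate)."""
    return NetworkConfig(
        n_units=4,
        weights=(0.0001, 0.0002, 0.00015, 0.00025),
        grid_shape=(2, 2),
    )


@pytest.fixture
def net16():
    return NetworkConfig.weakly_coupled(16, seed=1)


@pytest.fixture
def short_schedule():
    return PerturbationSchedule(redraw_interval=200, n_epochs=2, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
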