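import numpy as np
import pytest

from fnirs_vhdr import (
    generate_event_schedule,
    make_default_montage,
    simulate_subject,
    td_default_config,
)


@pytest.fixture(scope="session")
def montage():
    return make_default_montage()


@pytest.fixture(scope="session")
def schedule():
    return generate_event_schedule(20, 20, 5.0, 10.0, seed=1)


@pytest.fixture(scope="session")
def short_schedule():
    return generate_event_schedule(5, 5, 5.0, 10.0, seed=2)


@pytest.fixture(scope="session")
def noiseless_config():
    return td_default_config().noiseless()


@pytest.fixture(scope="session")
def noiseless_subject(montage, schedule, noiseless_config):
    """A noiseless simulated subject with lambda = 1.5 (default gain)."""
    return simulate_subject(montage, schedule, noiseless_config, seed=3)


@pytest.fixture(scope="session")
def noisy_subject(montage, schedule):
    return simulate_subject(montage, schedule, td_default_config(), seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
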