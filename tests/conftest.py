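import numpy as np
import pytest

from holosim.fixtures import (
    load_stage_table,
    make_clock_fixture,
    make_host_clock_fixture,
    make_slow_clock_fixture,
)


@pytest.fixture(scope="session")
def stage_table():
    return load_stage_table()


@pytest.fixture(scope="session")
def clock():
    """Period-4 deterministic clock genome with 50 household genes (L=64)."""
    return make_clock_fixture(households=50)


@pytest.fixture(scope="session")
def slow_clock():
    """Period-5 clock (one gap state), 24 household genes (L=40)."""
    return make_slow_clock_fixture(households=24)


@pytest.fixture(scope="session")
def host_clock():
    """Period-10 clock, 16 household genes (L=40)."""
    return make_host_clock_fixture(households=16)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
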