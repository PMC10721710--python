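import numpy as np
import pytest

from ecoqad import fixture_small


@pytest.fixture(scope="session")
def fixture_data():
    """Deterministic 40-plot, 12-variable community with one planted link
    of each class."""
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_table(fixture_data):
    return fixture_data[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
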