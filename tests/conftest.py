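import numpy as np
import pytest

from recsplice.simdata import (SimConfig, fixture_reference,
                               simulate_population, simulate_reference,
                               simulate_study)


@pytest.fixture(scope="session")
def minus_fixture():
    """Default (minus-strand) gene fixture embedded in a 4 kb chromosome."""
    return fixture_reference(strand="-")


@pytest.fixture(scope="session")
def plus_fixture():
    """The same gene mirrored onto the plus strand."""
    return fixture_reference(strand="+")


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_population(default_config):
    return simulate_population(default_config)


@pytest.fixture(scope="session")
def default_study(default_config):
    return simulate_study(default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
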