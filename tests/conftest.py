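import numpy as np
import pytest

from ssfir import DegreeDistribution, Network, generate_er


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path3():
    """0 - 1 - 2 path graph."""
    return Network(3, [(0, 1), (1, 2)])


@pytest.fixture
def poisson10():
    return DegreeDistribution.poisson(10.0)


@pytest.fixture(scope="session")
def er2000():
    """One shared medium ER graph (n=2000, <k>=10) for the heavier tests."""
    return generate_er(2000, 10.0, seed=20240915)


@pytest.fixture(scope="session")
def er200():
    return generate_er(200, 8.0, seed=7)
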