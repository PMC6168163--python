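import numpy as np
import pytest

from qorac import fixtures as qfx


@pytest.fixture(scope="session")
def example1():
    return qfx.example1()


@pytest.fixture(scope="session")
def chain7():
    return qfx.linear_chain(7, seed=0)


@pytest.fixture(scope="session")
def branched():
    return qfx.branched_network()


@pytest.fixture(scope="session")
def km_valid():
    return qfx.km_sensing_fixture(True)


@pytest.fixture(scope="session")
def km_invalid():
    return qfx.km_sensing_fixture(False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180920)
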