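import numpy as np
import pytest

from allomap import RunConfig, make_fixture, parse_ca_structure


@pytest.fixture(scope="session")
def coil30():
    return parse_ca_structure(make_fixture("coil", 30, 3), source="coil30")


@pytest.fixture(scope="session")
def coil20():
    return parse_ca_structure(make_fixture("coil", 20, 11), source="coil20")


@pytest.fixture(scope="session")
def helix20():
    return parse_ca_structure(make_fixture("helix", 20, 0), source="helix20")


@pytest.fixture(scope="session")
def dumbbell60():
    return parse_ca_structure(make_fixture("dumbbell", 60, 0), source="dumbbell60")


@pytest.fixture(scope="session")
def sym_dimer30():
    return parse_ca_structure(make_fixture("sym_dimer", 15, 7), source="sym_dimer30")


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
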