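import numpy as np
import pytest

from condfuse import ForceField, ThermoParams, make_fixture


@pytest.fixture
def ff():
    """Reference force field with Es = 10 kT, Ens = 0.3 kT."""
    return ForceField.from_kt(10.0, 0.3)


@pytest.fixture
def thermo():
    return ThermoParams()


@pytest.fixture
def dimer():
    return make_fixture("dimer")


@pytest.fixture
def microcluster():
    return make_fixture("microcluster-10")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
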