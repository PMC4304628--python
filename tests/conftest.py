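import numpy as np
import pytest

from trialvoi import ensemble as ens
from trialvoi import kinetics as kin


@pytest.fixture(scope="session")
def network():
    return kin.reference_selenium_network()


@pytest.fixture(scope="session")
def nominal(network):
    return kin.nominal_parameters(network)


@pytest.fixture(scope="session")
def constraint(network):
    return ens.CalibrationConstraint(
        target_dmDNA=ens.reference_damage_level(network))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
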