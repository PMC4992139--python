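import numpy as np
import pytest

from baseplate.restraints import EnergyModel, Weights
from baseplate.synthetic import make_fixture_bundle, make_helix_monomer


@pytest.fixture(scope="session")
def small_bundle():
    """Noiseless small fixture; shared (read-only) across the suite."""
    return make_fixture_bundle("small", seed=1)


@pytest.fixture(scope="session")
def small_model(small_bundle):
    return EnergyModel(small_bundle.monomer, small_bundle.restraints,
                       Weights(), small_bundle.extent)


@pytest.fixture(scope="session")
def helix12():
    return make_helix_monomer("ADSLVKTATGFL")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
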