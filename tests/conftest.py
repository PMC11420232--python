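import numpy as np
import pytest

from socialdiscounting.design import DesignConfig, OfferLattice


@pytest.fixture(scope="session")
def design_config():
    return DesignConfig()


@pytest.fixture(scope="session")
def lattice(design_config):
    # built once: 17,100 amount/delay combinations
    return OfferLattice(design_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
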