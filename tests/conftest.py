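import numpy as np
import pytest

from luminachip.geometry import ChipGeometry, build_domain_mask


@pytest.fixture(scope="session")
def geometry():
    return ChipGeometry()


@pytest.fixture(scope="session")
def mask10(geometry):
    """Default chip at 10 μm pitch — coarse but fast, shared across tests."""
    return build_domain_mask(geometry, 10.0)


@pytest.fixture(scope="session")
def mask5(geometry):
    return build_domain_mask(geometry, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
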