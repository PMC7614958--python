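"""Shared fixtures: small reference chains and synthetic owl datasets."""

import numpy as np
import pytest

from chainmeld.ipm import simulate_ipm
from chainmeld.phi import PhiLayout
from chainmeld.validation import DiscreteChainDemo, GaussianChainDemo


@pytest.fixture(scope="session")
def gauss_demo():
    """Conjugate Gaussian three-chain with logarithmic (1/2, 1/2, 1/2) pooling."""
    return GaussianChainDemo()


@pytest.fixture(scope="session")
def discrete_demo():
    """Fully discrete three-chain with enumerable melded posterior."""
    return DiscreteChainDemo()


@pytest.fixture(scope="session")
def owl_data():
    """A small simulated owls dataset (T = 10) plus the generating truth."""
    cr, counts, fec, truth = simulate_ipm(T=10, releases_per_stratum=40, seed=123)
    return cr, counts, fec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def layout2():
    """Two-overlap scalar layout shared by the small pooling examples."""
    return PhiLayout(("phi12", "phi23"), (1, 1))
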