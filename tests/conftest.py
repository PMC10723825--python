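import numpy as np
import pytest

from subsetfam.design import DesignMatrix
from subsetfam.posterior import PosteriorDraws


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_design(rng):
    """30 x 5 design with moderately correlated columns."""
    Z = rng.standard_normal((30, 5))
    Z[:, 1] += 0.5 * Z[:, 0]
    return DesignMatrix.from_array(Z)


@pytest.fixture(scope="session")
def toy_draws():
    """Tiny deterministic Gaussian posterior draws over 3 columns."""
    rng = np.random.default_rng(7)
    beta = np.array([1.0, 0.5, -0.25]) + 0.05 * rng.standard_normal((200, 3))
    sigma = np.full(200, 0.5) + 0.01 * rng.uniform(size=200)
    return PosteriorDraws(beta, sigma)
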