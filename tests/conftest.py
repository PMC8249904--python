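import numpy as np
import pytest

from sbci import build_grid, build_icosphere
from sbci.simulate import EndpointMixture, simulate_parcellation


@pytest.fixture(scope="session")
def level2_grid():
    """Two level-2 icospheres (162 vertices each), nothing masked out."""
    return build_grid(build_icosphere(2, "left"), build_icosphere(2, "right"))


@pytest.fixture(scope="session")
def level3_grid():
    """Two level-3 icospheres (642 vertices each)."""
    return build_grid(build_icosphere(3, "left"), build_icosphere(3, "right"))


@pytest.fixture(scope="session")
def level3_parcellation(level3_grid):
    return simulate_parcellation(level3_grid, 6, seed=1)


@pytest.fixture(scope="session")
def vmf_mixture(level3_parcellation):
    """Three product-vMF components between parcel centroids."""
    return EndpointMixture.from_parcellation(
        level3_parcellation, [(0, 7), (2, 9), (4, 5)], 50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
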