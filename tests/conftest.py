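import numpy as np
import pytest

from ctnet import ModelParameters, generate_connectome, generate_damage_maps


@pytest.fixture(scope="session")
def small_connectome():
    """A reduced connectome at the realistic edge density.

    32 regions is the smallest size at which the degree distribution is
    close enough to the full-scale network for the default coupling to keep
    its low-firing operating branch.
    """
    return generate_connectome(n_regions=32, edge_density=0.15, seed=7)


@pytest.fixture(scope="session")
def small_maps(small_connectome):
    return generate_damage_maps(small_connectome, wm_site_fraction=0.4, seed=3)


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
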