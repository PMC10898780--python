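import numpy as np
import pytest

import turbodyn as td


@pytest.fixture(scope="session")
def small_geometry():
    return td.make_geometry(20, seed=7)


@pytest.fixture(scope="session")
def medium_geometry():
    return td.make_geometry(60, seed=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_phase_field(small_geometry):
    """Random but reproducible phases on the small geometry."""
    r = np.random.default_rng(99)
    phi = r.uniform(-np.pi, np.pi, (small_geometry.n_nodes, 50))
    return phi
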