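import numpy as np
import pytest

import dictsir as ds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_geom():
    """10-view fan over a 8x8 grid: small enough for dense oracles."""
    return ds.build_geometry(10, 36.0, 12, 8, 2.0)


@pytest.fixture(scope="session")
def small_system(small_geom):
    return ds.build_system_matrix(small_geom)


@pytest.fixture(scope="session")
def toy_geom32():
    """32x32 toy protocol used by the lambda-monotonicity checks."""
    return ds.build_geometry(30, 12.0, 64, 32, 2.0)


@pytest.fixture(scope="session")
def toy_system32(toy_geom32):
    return ds.build_system_matrix(toy_geom32)


@pytest.fixture(scope="session")
def phantom32():
    return 0.07 * ds.make_shepp_logan(32)
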