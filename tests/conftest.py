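import numpy as np
import pytest

from mparamap import mrs, phantom


@pytest.fixture(scope="session")
def gbm_truth():
    """Noiseless default GBM phantom (64x64, 5 slices, two mirrored discs)."""
    return phantom.make_phantom(phantom.default_phantom_spec())


@pytest.fixture(scope="session")
def small_truth():
    """Small noiseless GBM phantom for per-pixel fitting tests."""
    spec = phantom.default_phantom_spec(grid_shape=(24, 24), n_slices=2, radius_px=4.0)
    return phantom.make_phantom(spec)


@pytest.fixture(scope="session")
def basis():
    return mrs.default_basis()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
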