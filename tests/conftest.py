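import numpy as np
import pytest

from neurimine import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_phantom():
    """A quiet 32-cubed single-neurite phantom shared by read-only tests."""
    cfg = PhantomConfig(shape=(32, 32, 32), n_neurites=1, seed=7,
                        gauss_sigma_noise=5.0, dim_fraction=0.0)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def straight_tube():
    """Noise-free straight axial tube: exact centerline, no dim stretch."""
    cfg = PhantomConfig(shape=(24, 24, 48), n_neurites=1, seed=3,
                        gauss_sigma_noise=0.0, dim_fraction=0.0,
                        radius_range=(2.0, 2.0), straight_axial=True)
    return generate_phantom(cfg)
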