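import numpy as np
import pytest

from vesselsnake import (
    EnergyParams,
    PhantomSpec,
    ScaleParams,
    fit_histogram_gmm,
    make_phantom,
)
from vesselsnake.phantoms import default_seed_mask


@pytest.fixture(scope="session")
def clean_tube():
    """Zero-noise straight tube, 64x64, with ground truth and seed."""
    spec = PhantomSpec(shape=(64, 64), noise_sigma=0.0, geometry="straight")
    image, truth = make_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noisy_tube():
    """Straight tube at contrast = 4 sigma, 96x96."""
    spec = PhantomSpec(shape=(96, 96), noise_sigma=25.0, geometry="straight", rng_seed=7)
    image, truth = make_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def leak_phantom():
    """Tube with tangent bright blob (the leak trap), 96x96."""
    spec = PhantomSpec(
        shape=(96, 96), noise_sigma=25.0, geometry="straight_plus_blob", rng_seed=3
    )
    image, truth = make_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_tube_model(clean_tube):
    _, image, _ = clean_tube
    return fit_histogram_gmm(image, n_components=2, seed=0)


@pytest.fixture(scope="session")
def noisy_tube_model(noisy_tube):
    _, image, _ = noisy_tube
    return fit_histogram_gmm(image, n_components=3, seed=0)


@pytest.fixture
def seed_of():
    return default_seed_mask


@pytest.fixture
def quick_params():
    """Short evolution budget for unit-level integration tests."""
    return EnergyParams(max_iters=150)


@pytest.fixture
def scale():
    return ScaleParams()
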