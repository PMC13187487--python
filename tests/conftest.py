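import numpy as np
import pytest

from vistaz import PhantomSpec, ProjectionImage, VesselMask, generate


@pytest.fixture(scope="session")
def grid_phantom():
    """Standard ISV-ladder phantom: 10 rungs, width 5 px, SNR ≈ 6.7."""
    return generate(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_bar_phantom():
    """Noise-free, blur-free straight bar, width 5, for exact geometry checks."""
    return generate(
        PhantomSpec(topology="bar", psf_sigma_px=0.0, noise_model="none", seed=0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_projection(pixels, bit_depth=8, **kw):
    return ProjectionImage(pixels=np.asarray(pixels), bit_depth=bit_depth, **kw)


def make_mask(pixels):
    return VesselMask(np.asarray(pixels, dtype=bool))


@pytest.fixture
def projection_factory():
    return make_projection


@pytest.fixture
def mask_factory():
    return make_mask
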