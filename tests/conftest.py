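import numpy as np
import pytest

from edxmix import (
    EnergyAxis,
    HyperspectralCube,
    default_phantom,
    five_structure_phantom,
    render_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    return EnergyAxis(offset_ev=100.0, bin_width_ev=10.0, n_channels=32)


@pytest.fixture
def small_cube(rng, small_axis):
    """Random integer 8x8x32 cube with full metadata."""
    counts = rng.poisson(5.0, size=(8, 8, 32)).astype(np.uint32)
    return HyperspectralCube(
        counts=counts,
        energy=small_axis,
        pixel_size_nm=4.0,
        n_frames=3,
        dwell_us=100.0,
        tile_id="t00",
    )


@pytest.fixture(scope="session")
def phantom_small():
    """Small noisy 4-foreground-class phantom + ground truth, rendered once."""
    spec = default_phantom(shape=(64, 64), counts_per_pixel_per_frame=250.0, n_frames=8, seed=7)
    cube, gt = render_phantom(spec)
    return spec, cube, gt


@pytest.fixture(scope="session")
def phantom_noiseless():
    spec = default_phantom(shape=(48, 48), counts_per_pixel_per_frame=200.0, n_frames=4, seed=3)
    cube, gt = render_phantom(spec, noiseless=True)
    return spec, cube, gt


@pytest.fixture(scope="session")
def phantom_five():
    spec = five_structure_phantom(shape=(96, 96), counts_per_pixel_per_frame=250.0, n_frames=10, seed=11)
    cube, gt = render_phantom(spec)
    return spec, cube, gt
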