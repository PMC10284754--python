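import numpy as np
import pytest

from luquant.phantom import (
    PhantomSpec,
    ReconVariant,
    SphereSpec,
    default_phantom,
    rasterize_phantom,
)

SMALL_GRID = (64, 64, 40)
VOX = 4.8


def small_grid_center():
    return (np.asarray(SMALL_GRID, float) - 1) / 2.0 * VOX


@pytest.fixture(scope="session")
def single_sphere28():
    """One ø28 sphere, no background, on a compact grid."""
    center = tuple(small_grid_center())
    spec = PhantomSpec(
        spheres=(SphereSpec(center=center, diameter=28.0, true_concentration=514.0),),
        label="single28",
    )
    return spec


@pytest.fixture(scope="session")
def truth28(single_sphere28):
    return rasterize_phantom(
        single_sphere28, voxel_size=VOX, grid_shape=SMALL_GRID, supersampling=4
    )


@pytest.fixture(scope="session")
def nema_phantom():
    """The full six-sphere phantom on the default 128x128x80 grid."""
    return default_phantom()


@pytest.fixture(scope="session")
def nema_truth(nema_phantom):
    return rasterize_phantom(nema_phantom, supersampling=4)


@pytest.fixture(scope="session")
def smoothed_noiseless(nema_phantom, nema_truth):
    """Noiseless smoothed-variant image of the six-sphere phantom."""
    from luquant.phantom import apply_recon_variant

    variant = ReconVariant("smoothed", psf_fwhm=12.0, post_filter_fwhm=10.0)
    return apply_recon_variant(nema_truth, variant)
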