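import numpy as np
import pytest

from octvessel import SyntheticVesselSpec


@pytest.fixture
def artery_spec():
    """A typical arteriole phantom at device-like blur, noiseless."""
    return SyntheticVesselSpec(
        outer_diameter=147.0, lumen_diameter=114.0, psf_sigma=2.0, pixel_pitch=5.0
    )


@pytest.fixture
def vein_spec():
    return SyntheticVesselSpec(
        outer_diameter=178.0, lumen_diameter=150.0, psf_sigma=2.0, pixel_pitch=5.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240819)


def random_vessel_spec(rng, sigma_range=(0.0, 8.0), speckle_shape=None, seed=0):
    """Draw a realistic random vessel geometry (walls 12-20 µm, lumen 100-160 µm)."""
    wall = rng.uniform(12.0, 20.0)
    lumen = rng.uniform(100.0, 160.0)
    return SyntheticVesselSpec(
        outer_diameter=lumen + 2 * wall,
        lumen_diameter=lumen,
        psf_sigma=rng.uniform(*sigma_range),
        pixel_pitch=5.0,
        speckle_shape=speckle_shape,
        seed=seed,
    )
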