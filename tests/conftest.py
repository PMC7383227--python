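import numpy as np
import pytest

from junctionmech import synthetic as syn
from junctionmech import tfm


@pytest.fixture
def gel() -> tfm.GelProperties:
    """TFM-grade polyacrylamide gel (16.4 kPa, near-incompressible)."""
    return tfm.GelProperties(youngs_modulus_pa=16400.0, poisson_ratio=0.5)


@pytest.fixture
def noiseless_scene():
    """Factory for scenes with imaging noise disabled."""
    def make(size=128, pixel_size_um=2.6, seed=0):
        return syn.SceneParams(image_size_px=(size, size),
                               pixel_size_um=pixel_size_um, rng_seed=seed,
                               noise_model=syn.NoiseModel(gaussian_sd=0.0))
    return make


@pytest.fixture
def smooth_dipole():
    """Force-balanced Gaussian dipole without a hard footprint edge.

    Band-limited on the grid, so spectral and direct-space evaluations of
    the Boussinesq convolution can be compared at sub-percent level.
    """
    def make(n=64, spacing_um=2.6, magnitude_pa=100.0):
        coords = np.arange(n) * spacing_um
        gy, gx = np.meshgrid(coords, coords, indexing="ij")
        cy, cx = coords.mean(), coords.mean()
        sig = 4.0 * spacing_um
        offset = 4.0 * spacing_um
        lobe_r = np.exp(-(((gx - cx) - offset) ** 2 + (gy - cy) ** 2)
                        / (2 * sig ** 2))
        lobe_l = np.exp(-(((gx - cx) + offset) ** 2 + (gy - cy) ** 2)
                        / (2 * sig ** 2))
        t_x = magnitude_pa * (lobe_l - lobe_r)
        t_x -= t_x.mean()
        return tfm.TractionField(t_x=t_x, t_y=np.zeros_like(t_x),
                                 grid_spacing_um=spacing_um)
    return make
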