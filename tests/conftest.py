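"""Shared fixtures: analytic phantoms and a coarse pipeline config for
fast unit tests (acceptance tests use the default 0.1-degree grid)."""

import numpy as np
import pytest

from cellpolar import (CellGeometrySpec, CellMasks, ImagePlane,
                       OrganelleFieldSpec, PipelineConfig, generate_masks,
                       render_image)

# coarser sweep for unit tests where the checked tolerance allows it
COARSE = dict(theta_step_deg=0.5, radial_step_px=0.5, u_step=0.5)


@pytest.fixture
def coarse_config() -> PipelineConfig:
    return PipelineConfig(**COARSE)


@pytest.fixture
def disk_cell():
    """Uniform unit-intensity disk (R = 60 px) with a small central nucleus."""
    H = W = 160
    center = (80.0, 80.0)
    R = 60.0
    rows, cols = np.indices((H, W), dtype=float)
    r = np.hypot(rows - center[0], cols - center[1])
    disk = r <= R
    nucleus = r <= 6.0
    image = ImagePlane(disk.astype(float), pixel_size=0.1)
    masks = CellMasks(nucleus=nucleus, cell=disk,
                      exclusion=np.zeros_like(disk), center=center)
    return image, masks, R


@pytest.fixture
def symmetric_phantom():
    """Noise-free perinuclear phantom with perfect angular symmetry."""
    geom = CellGeometrySpec()
    field = OrganelleFieldSpec(w_perinuclear=0.7, w_peripheral=0.0,
                               w_uniform=0.3, angular_kappa=0.0,
                               read_noise_sd=0.0, background=0.0)
    image = render_image(geom, field, seed=0, shot_noise=False)
    return geom, field, image, generate_masks(geom)


@pytest.fixture
def asymmetric_phantom():
    """Noise-free phantom with angular bias and irregular geometry."""
    geom = CellGeometrySpec(nucleus_center=(126.0, 131.0), nucleus_angle=0.7,
                            cell_shape_coeffs=[(2, 0.06, 0.3), (3, -0.05, 1.1)])
    field = OrganelleFieldSpec(angular_kappa=1.5, angular_mu=0.9,
                               read_noise_sd=0.0, background=0.0)
    image = render_image(geom, field, seed=0, shot_noise=False)
    return geom, field, image, generate_masks(geom)


def cartesian_mdr_um(image: ImagePlane, center) -> float:
    """Brute-force pixel-binning oracle: intensity-weighted mean distance
    of whole pixels from the center, in micrometers.  Independent of the
    line-profile polar code path."""
    rows, cols = np.indices(image.shape, dtype=float)
    rad = np.hypot(rows - center[0], cols - center[1])
    total = image.pixels.sum()
    return float((image.pixels * rad).sum() / total * image.pixel_size)
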