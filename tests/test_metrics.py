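"""Spatial PMF construction and the MDR / asymmetry statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellpolar import (CellGeometrySpec, EmptySignalError, ImagePlane,
                       OrganelleFieldSpec, PipelineConfig, UsageError,
                       asymmetry, boundary_radii, generate_masks,
                       ground_truth_metrics, locate_center,
                       mean_distribution_radius, normalize_radial,
                       quantify_cell, render_image, sweep_polar, to_pmf)
from cellpolar.polar import NormalizedPolarMap

from .conftest import COARSE


def _nmap_for(image, masks, theta_step=0.5):
    c = locate_center(masks)
    pmap = sweep_polar(image, c, theta_step=theta_step, cell_mask=masks.cell)
    br = boundary_radii(masks, c, theta_step=theta_step)
    return normalize_radial(pmap, br)


def _single_angle_nmap(n_theta=360, n_u=251):
    """All mass on one angular row: the degenerate fully-asymmetric case."""
    values = np.zeros((n_theta, n_u))
    values[17, 40:60] = 1.0
    weight = np.ones_like(values)
    u = np.linspace(-25, 100, n_u)
    theta = np.deg2rad(np.arange(n_theta) * (360.0 / n_theta))
    return NormalizedPolarMap(values=values, weight=weight,
                              raw_radius=np.ones_like(values), u=u,
                              theta=theta, u_step=0.5, center=(0.0, 0.0),
                              pixel_size=1.0)


class TestToPmf:
    def test_sums_to_one(self, disk_cell):
        image, masks, _ = disk_cell
        pmf = to_pmf(_nmap_for(image, masks))
        assert pmf.p.sum() == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(0.1, 1000.0))
    @settings(deadline=None, max_examples=15)
    def test_scale_invariance(self, c):
        nmap = _single_angle_nmap()
        base = to_pmf(nmap)
        scaled = NormalizedPolarMap(values=nmap.values * c, weight=nmap.weight,
                                    raw_radius=nmap.raw_radius, u=nmap.u,
                                    theta=nmap.theta, u_step=nmap.u_step,
                                    center=nmap.center, pixel_size=nmap.pixel_size)
        np.testing.assert_allclose(to_pmf(scaled).p, base.p)

    def test_cytoplasm_only_restricts_domain(self, disk_cell):
        image, masks, _ = disk_cell
        pmf = to_pmf(_nmap_for(image, masks), domain="cytoplasm_only")
        assert np.all(pmf.u >= 0)
        assert pmf.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_signal_raises(self, disk_cell):
        _, masks, _ = disk_cell
        blank = ImagePlane(np.zeros(masks.cell.shape), pixel_size=0.1)
        with pytest.raises(EmptySignalError):
            to_pmf(_nmap_for(blank, masks))


class TestMdr:
    def test_uniform_cytoplasm_normalized_50(self):
        # density uniform in the normalized coordinate: mean of U[0, 100]
        geom = CellGeometrySpec()
        field = OrganelleFieldSpec(w_perinuclear=0, w_peripheral=0, w_uniform=1,
                                   read_noise_sd=0.0, background=0.0)
        image = render_image(geom, field, seed=0, shot_noise=False)
        pmf = to_pmf(_nmap_for(image, generate_masks(geom)))
        assert mean_distribution_radius(pmf, "normalized") == pytest.approx(
            50.0, abs=1.0)

    def test_uniform_area_disk_normalized_mean(self, disk_cell):
        # uniform intensity per AREA over a disk with a tiny nucleus:
        # E[u] = 100 (E[r] - r_ne) / (R - r_ne) with E[r] = 2R/3
        image, masks, R = disk_cell
        pmf = to_pmf(_nmap_for(image, masks), domain="cytoplasm_only")
        r_ne = 6.0
        expected = 100.0 * (2.0 * R / 3.0 - r_ne) / (R - r_ne)
        assert mean_distribution_radius(pmf, "normalized") == pytest.approx(
            expected, rel=0.02)

    def test_uniform_disk_raw_two_thirds_R(self, disk_cell):
        image, masks, R = disk_cell
        pmf = to_pmf(_nmap_for(image, masks), domain="full")
        expected = (2.0 / 3.0) * R * image.pixel_size
        assert mean_distribution_radius(pmf, "raw") == pytest.approx(
            expected, rel=0.01)

    def test_unknown_scale_rejected(self, disk_cell):
        image, masks, _ = disk_cell
        pmf = to_pmf(_nmap_for(image, masks))
        with pytest.raises(UsageError):
            mean_distribution_radius(pmf, "furlongs")


class TestAsymmetry:
    def test_symmetric_phantom_near_zero(self, symmetric_phantom):
        _, _, image, masks = symmetric_phantom
        asym, _ = asymmetry(to_pmf(_nmap_for(image, masks)))
        assert asym < 0.02

    def test_single_angle_mass_is_one(self):
        asym, ang = asymmetry(to_pmf(_single_angle_nmap()))
        assert asym == pytest.approx(1.0, abs=1e-6)
        assert ang == pytest.approx(np.deg2rad(17.0), abs=1e-9)

    def test_matches_oracle_for_von_mises(self):
        geom = CellGeometrySpec()
        field = OrganelleFieldSpec(angular_kappa=2.0, w_perinuclear=1.0,
                                   w_uniform=0.0, u0=20, sigma_u=5,
                                   read_noise_sd=0.0, background=0.0)
        truth = ground_truth_metrics(geom, field)
        image = render_image(geom, field, seed=1, shot_noise=False)
        asym, _ = asymmetry(to_pmf(_nmap_for(image, generate_masks(geom))))
        assert asym == pytest.approx(truth.asymmetry, rel=0.03)


class TestQuantifyCell:
    def test_deterministic(self, asymmetric_phantom):
        _, _, image, masks = asymmetric_phantom
        cfg = PipelineConfig(**COARSE)
        assert quantify_cell(image, masks, cfg) == quantify_cell(image, masks, cfg)

    def test_clustered_twin_raises_asymmetry_not_mdr(self):
        geom = CellGeometrySpec()
        kw = dict(w_perinuclear=0.7, w_peripheral=0.0, w_uniform=0.3,
                  u0=14, sigma_u=6, read_noise_sd=0.0, background=0.0)
        twin = OrganelleFieldSpec(angular_kappa=0.0, **kw)
        clus = OrganelleFieldSpec(angular_kappa=2.5, angular_mu=1.0, **kw)
        cfg = PipelineConfig(**COARSE)
        masks = generate_masks(geom)
        m_twin = quantify_cell(render_image(geom, twin, 0, shot_noise=False),
                               masks, cfg)
        m_clus = quantify_cell(render_image(geom, clus, 0, shot_noise=False),
                               masks, cfg)
        assert m_clus.asymmetry > m_twin.asymmetry + 0.5
        assert m_clus.mdr_normalized == pytest.approx(m_twin.mdr_normalized,
                                                      rel=0.03)

    def test_mdr_monotone_in_peripheral_weight(self):
        # parameter ladder: more peripheral weight, larger MDR
        geom = CellGeometrySpec()
        masks = generate_masks(geom)
        cfg = PipelineConfig(**COARSE)
        mdrs = []
        for w_per in (0.0, 0.3, 0.6):
            field = OrganelleFieldSpec(w_perinuclear=0.7 - w_per,
                                       w_peripheral=w_per, w_uniform=0.3,
                                       read_noise_sd=0.0, background=0.0)
            img = render_image(geom, field, 0, shot_noise=False)
            mdrs.append(quantify_cell(img, masks, cfg).mdr_normalized)
        assert mdrs[0] < mdrs[1] < mdrs[2]

    def test_asymmetry_monotone_in_kappa(self):
        geom = CellGeometrySpec()
        masks = generate_masks(geom)
        cfg = PipelineConfig(**COARSE)
        asyms = []
        for kappa in (0.0, 0.8, 2.0, 4.0):
            field = OrganelleFieldSpec(angular_kappa=kappa, read_noise_sd=0.0,
                                       background=0.0)
            img = render_image(geom, field, 0, shot_noise=False)
            asyms.append(quantify_cell(img, masks, cfg).asymmetry)
        assert all(a < b for a, b in zip(asyms, asyms[1:]))

    def test_stage_error_names_stage(self, disk_cell):
        from cellpolar import StageError
        image, masks, _ = disk_cell
        blank = ImagePlane(np.zeros(image.shape), pixel_size=0.1)
        with pytest.raises(StageError, match="to_pmf"):
            quantify_cell(blank, masks, PipelineConfig(**COARSE))
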