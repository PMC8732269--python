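"""Phantom generator: masks, rendering, quadrature oracle, presets."""

import numpy as np
import pytest
from scipy.special import i0, i1

from cellpolar import (CellGeometrySpec, InvalidGeometryError, NeighborSpec,
                       OrganelleFieldSpec, UsageError, generate_masks,
                       ground_truth_metrics, ground_truth_panel,
                       make_phenotype_panel, render_image)


class TestGenerateMasks:
    def test_circular_nucleus_area(self):
        geom = CellGeometrySpec(nucleus_semiaxes=(20.0, 20.0),
                                cell_radius_base=80.0)
        masks = generate_masks(geom)
        assert masks.nucleus.sum() == pytest.approx(np.pi * 20**2, rel=0.02)

    def test_nucleus_contained_in_cell(self):
        geom = CellGeometrySpec(nucleus_angle=0.9,
                                cell_shape_coeffs=[(3, 0.1, 0.5), (5, -0.08, 2.0)])
        masks = generate_masks(geom)
        assert not np.any(masks.nucleus & ~masks.cell)

    def test_neighbor_blob_disjoint_from_nucleus(self):
        nb = NeighborSpec(center=(15.0, 240.0), semiaxes=(30.0, 22.0),
                          angle=0.3, intensity=1e5)
        masks = generate_masks(CellGeometrySpec(neighbor_specs=[nb]))
        assert masks.exclusion.any()
        assert not np.any(masks.exclusion & masks.nucleus)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidGeometryError):
            CellGeometrySpec(cell_shape_coeffs=[(2, 0.3, 0.0), (3, 0.25, 0.0)])
        with pytest.raises(InvalidGeometryError):
            CellGeometrySpec(nucleus_semiaxes=(85.0, 85.0))  # no cytoplasm
        with pytest.raises(InvalidGeometryError):
            CellGeometrySpec(nucleus_center=(10.0, 128.0))  # nucleus off image


class TestRenderImage:
    def test_noise_free_total_matches_budget(self):
        field = OrganelleFieldSpec(photon_budget=1e6, background=0.0,
                                   read_noise_sd=0.0)
        img = render_image(CellGeometrySpec(), field, seed=0, shot_noise=False)
        assert img.total_intensity() == pytest.approx(1e6, rel=0.01)

    def test_background_adds_cell_area_counts(self):
        geom = CellGeometrySpec()
        field = OrganelleFieldSpec(photon_budget=1e6, background=2.0,
                                   read_noise_sd=0.0)
        img = render_image(geom, field, seed=0, shot_noise=False)
        area = generate_masks(geom).cell.sum()
        assert img.total_intensity() == pytest.approx(1e6 + 2.0 * area, rel=0.01)

    def test_kappa_zero_angular_marginal_uniform(self):
        geom = CellGeometrySpec()
        field = OrganelleFieldSpec(angular_kappa=0.0, background=0.0,
                                   read_noise_sd=0.0)
        img = render_image(geom, field, seed=0, shot_noise=False)
        rows, cols = np.indices(img.shape, dtype=float)
        theta = np.arctan2(rows - geom.nucleus_center[0],
                           cols - geom.nucleus_center[1])
        bins = np.linspace(-np.pi, np.pi, 37)
        marginal, _ = np.histogram(theta, bins=bins, weights=img.pixels)
        assert marginal.std() / marginal.mean() < 0.05

    def test_same_seed_bit_identical(self):
        geom, field = CellGeometrySpec(), OrganelleFieldSpec()
        a = render_image(geom, field, seed=42)
        b = render_image(geom, field, seed=42)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_noise_is_poisson_plus_read(self):
        # variance of repeated noisy renders tracks the expected signal
        geom = CellGeometrySpec()
        field = OrganelleFieldSpec(photon_budget=5e5, background=0.0,
                                   read_noise_sd=3.0)
        clean = render_image(geom, field, seed=0, shot_noise=False)
        reps = np.stack([render_image(geom, field, seed=s).pixels
                         for s in range(40)])
        sel = clean.pixels > 50
        var = reps.var(axis=0)[sel]
        expected = clean.pixels[sel] + 3.0**2
        assert np.median(var / expected) == pytest.approx(1.0, abs=0.15)


class TestGroundTruth:
    def test_uniform_cytoplasm_mdr_is_50(self):
        field = OrganelleFieldSpec(w_perinuclear=0, w_peripheral=0, w_uniform=1,
                                   angular_kappa=0.0)
        truth = ground_truth_metrics(CellGeometrySpec(), field)
        assert truth.mdr_normalized == pytest.approx(50.0, abs=1e-6)
        assert truth.asymmetry == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_asymmetry_closed_form(self):
        # mean resultant length of von Mises(kappa) is I1(kappa)/I0(kappa)
        for kappa in (0.5, 2.0, 4.0):
            field = OrganelleFieldSpec(w_perinuclear=1, w_peripheral=0,
                                       w_uniform=0, u0=20, sigma_u=5,
                                       angular_kappa=kappa)
            truth = ground_truth_metrics(CellGeometrySpec(), field)
            assert truth.asymmetry == pytest.approx(i1(kappa) / i0(kappa),
                                                    rel=1e-6)

    def test_asymmetry_invariant_to_mu_and_mdr_to_rotation(self):
        field_a = OrganelleFieldSpec(angular_kappa=2.0, angular_mu=0.3)
        field_b = OrganelleFieldSpec(angular_kappa=2.0, angular_mu=2.9)
        geom = CellGeometrySpec(nucleus_angle=0.4,
                                cell_shape_coeffs=[(2, 0.08, 0.6)])
        rot = CellGeometrySpec(nucleus_angle=0.4 + 1.1,
                               cell_shape_coeffs=[(2, 0.08, 0.6 + 2 * 1.1)])
        ta, tb = ground_truth_metrics(geom, field_a), ground_truth_metrics(geom, field_b)
        assert ta.asymmetry == pytest.approx(tb.asymmetry, rel=1e-9)
        # rotating the whole geometry leaves the (symmetric-density) raw MDR alone
        sym = OrganelleFieldSpec(angular_kappa=0.0)
        assert ground_truth_metrics(geom, sym).mdr_raw == pytest.approx(
            ground_truth_metrics(rot, sym).mdr_raw, rel=1e-6)

    def test_truncated_gaussian_mean_vs_brute_force(self):
        # independent dense-sum oracle for the mixture mean in u
        field = OrganelleFieldSpec(w_perinuclear=0.6, w_peripheral=0.3,
                                   w_uniform=0.1, u0=18, sigma_u=6,
                                   u1=78, sigma_u1=9)
        u = np.linspace(0, 100, 400001)
        f = field.radial_density(u)
        brute = np.trapezoid(u * f, u) / np.trapezoid(f, u)
        truth = ground_truth_metrics(CellGeometrySpec(), field)
        assert truth.mdr_normalized == pytest.approx(brute, rel=1e-6)

    def test_field_invariants_enforced(self):
        with pytest.raises(UsageError):
            OrganelleFieldSpec(w_perinuclear=0.5, w_peripheral=0.5, w_uniform=0.5)
        with pytest.raises(UsageError):
            OrganelleFieldSpec(angular_kappa=-1.0)
        with pytest.raises(UsageError):
            OrganelleFieldSpec(photon_budget=0.0)


class TestPhenotypePanels:
    def test_preset_ordering_via_oracle(self):
        wt = ground_truth_panel("wildtype", 20, seed=5)
        disp = ground_truth_panel("dispersed", 20, seed=5)
        clus = ground_truth_panel("clustered", 20, seed=5)
        assert np.mean([g.mdr_normalized for g in disp]) > \
            np.mean([g.mdr_normalized for g in wt])
        assert np.mean([g.asymmetry for g in clus]) > \
            np.mean([g.asymmetry for g in wt])

    def test_panel_deterministic(self):
        a = make_phenotype_panel("wildtype", 1, seed=9)
        b = make_phenotype_panel("wildtype", 1, seed=9)
        assert a[0].truth == b[0].truth
        np.testing.assert_array_equal(a[0].image.pixels, b[0].image.pixels)

    def test_substreams_stable_under_panel_size(self):
        # cell i is identical whether the panel has 2 or 5 cells
        small = make_phenotype_panel("clustered", 2, seed=4, noise=False)
        large = make_phenotype_panel("clustered", 5, seed=4, noise=False)
        np.testing.assert_array_equal(small[1].image.pixels,
                                      large[1].image.pixels)

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(UsageError):
            make_phenotype_panel("mystery", 3, seed=0)
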