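"""Segmentation, sphere-model fitting and derived biophysics."""

import numpy as np
import pytest
from scipy import integrate

from holocyte import (CellPhantom, FitSettings, OpticalConfig, QCRules,
                      center_phantom, compute_dry_mass, compute_form_factor,
                      compute_volume, fit_sphere_model, form_factor,
                      qc_filter, render_phase_image, segment_cells)
from holocyte.imaging import PhaseImage
from holocyte.morpho import CellMask, CellMeasurement, sphere_model_sse


# ------------------------------------------------------------- formulas

class TestVolume:
    def test_zero_radius(self):
        assert compute_volume(0.0) == 0.0

    @pytest.mark.parametrize("r, expect", [(3.675, 207.9), (4.533, 390.1)])
    def test_reference_radii(self, r, expect):
        assert compute_volume(r) == pytest.approx(expect, abs=0.1)

    def test_agrees_with_numerical_integration(self):
        r = 3.675
        # integrate the chord length 2*sqrt(r^2 - rho^2) over the disk
        val, _ = integrate.quad(
            lambda rho: 2 * np.sqrt(r**2 - rho**2) * 2 * np.pi * rho, 0, r)
        assert compute_volume(r) == pytest.approx(val, rel=1e-8)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            compute_volume(-1.0)


class TestDryMass:
    def test_zero_contrast_gives_zero(self):
        assert compute_dry_mass(212.0, 1.337, 1.337) == 0.0

    def test_reference_value(self):
        # V=212 µm³, n_cell=1.3497 in buffer 1.337, alpha=0.2 -> 13.5 pg
        dm = compute_dry_mass(212.0, 1.3497, 1.337)
        assert dm == pytest.approx(212.0 / 0.2 * 0.0127, rel=1e-9)
        assert dm == pytest.approx(13.5, abs=0.05)

    def test_additive_in_volume(self):
        a = compute_dry_mass(100.0, 1.35, 1.337)
        b = compute_dry_mass(150.0, 1.35, 1.337)
        assert compute_dry_mass(250.0, 1.35, 1.337) == pytest.approx(a + b)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            compute_dry_mass(100.0, 1.35, 1.337, alpha_um3_per_pg=0.0)


class TestFormFactor:
    def test_analytic_circle_is_one(self):
        r = 3.675
        assert form_factor(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)

    def test_rasterized_circle_close_to_one(self):
        from skimage.draw import disk
        m = np.zeros((160, 160), bool)
        rr, cc = disk((80, 80), 36.9)
        m[rr, cc] = True
        _, _, ff = compute_form_factor(m, pixel_scale_um=0.1)
        assert ff == pytest.approx(1.0, abs=0.02)

    def test_square_mask(self):
        m = np.zeros((128, 128), bool)
        m[14:114, 14:114] = True
        _, _, ff = compute_form_factor(m, pixel_scale_um=0.1)
        assert ff == pytest.approx(np.pi / 4, abs=0.02)

    @pytest.mark.parametrize("ratio, expect", [(2.0, 0.8412), (3.0, 0.6631)])
    def test_ellipse_matches_ramanujan_perimeter(self, ratio, expect):
        # oracle: FF = 4*pi*(pi*a*b) / P_ramanujan^2
        from skimage.draw import ellipse
        a_px, b_px = 30 * ratio, 30
        m = np.zeros((256, 256), bool)
        rr, cc = ellipse(128, 128, b_px, a_px)
        m[rr, cc] = True
        h = ((a_px - b_px) / (a_px + b_px)) ** 2
        p_ram = np.pi * (a_px + b_px) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        assert 4 * np.pi * (np.pi * a_px * b_px) / p_ram**2 == \
            pytest.approx(expect, abs=5e-4)
        _, _, ff = compute_form_factor(m, pixel_scale_um=0.1)
        assert ff == pytest.approx(expect, abs=0.02)

    @pytest.mark.parametrize("radius_px", [15, 25, 40, 60])
    def test_clipped_ff_never_exceeds_one(self, radius_px):
        from skimage.draw import disk
        m = np.zeros((160, 160), bool)
        rr, cc = disk((80, 80), radius_px)
        m[rr, cc] = True
        _, _, ff = compute_form_factor(m, pixel_scale_um=0.1)
        assert 0.9 < ff <= 1.0


# --------------------------------------------------------- segmentation

class TestSegmentation:
    def test_single_phantom_area(self, lymph_phase, lymph_phantom):
        masks = segment_cells(lymph_phase)
        assert len(masks) == 1
        expect = np.pi * lymph_phantom.radius_um**2
        assert masks[0].area_um2 == pytest.approx(expect, rel=0.03)
        assert not masks[0].attached

    def test_empty_image(self, config):
        img = PhaseImage(np.zeros(config.image_shape), config.pixel_scale_um)
        assert segment_cells(img) == []

    def test_overlapping_phantoms_flagged_attached(self):
        cfg = OpticalConfig(image_shape=(192, 192))
        s = cfg.pixel_scale_um
        a = CellPhantom((8.0, 9.5), 3.675, 1.3497)
        b = CellPhantom((14.0, 9.5), 3.675, 1.3497)
        img = render_phase_image([a, b], cfg)
        masks = segment_cells(img)
        assert len(masks) == 1
        assert masks[0].attached

    def test_masks_ordered_row_major(self):
        cfg = OpticalConfig(image_shape=(256, 256))
        tops = CellPhantom((6.0, 6.0), 3.675, 1.3497)
        bottom = CellPhantom((18.0, 18.0), 3.675, 1.3497)
        img = render_phase_image([bottom, tops], cfg)
        masks = segment_cells(img)
        assert len(masks) == 2
        assert masks[0].centroid_px[0] < masks[1].centroid_px[0]


# ----------------------------------------------------------------- fit

class TestSphereFit:
    def test_noiseless_recovery_below_0p1_percent(self, lymph_phase,
                                                  lymph_phantom, config):
        masks = segment_cells(lymph_phase)
        m = fit_sphere_model(lymph_phase, masks[0], config)
        assert m.radius_um == pytest.approx(lymph_phantom.radius_um, rel=1e-3)
        assert m.n_cell == pytest.approx(lymph_phantom.n_cell, abs=1.4e-3)
        assert abs(m.radius_um / lymph_phantom.radius_um - 1) < 1e-3
        assert abs(m.n_cell - lymph_phantom.n_cell) / (
            lymph_phantom.n_cell - config.n_medium) * 0.0127 < 1.4e-3
        assert m.residual_rms < 1e-6
        assert "fit_failed" not in m.qc_flags
        # stored derived values satisfy their defining formulas exactly
        assert m.volume_um3 == compute_volume(m.radius_um)
        assert m.dry_mass_pg == compute_dry_mass(m.volume_um3, m.n_cell,
                                                 config.n_medium)

    def test_agrees_with_grid_search_oracle(self, lymph_phase, lymph_phantom,
                                            config):
        masks = segment_cells(lymph_phase)
        m = fit_sphere_model(lymph_phase, masks[0], config)
        from scipy import ndimage
        interior = ndimage.binary_erosion(masks[0].mask, iterations=2)
        x0, y0 = lymph_phantom.center_um
        r_grid = np.arange(lymph_phantom.radius_um - 0.05,
                           lymph_phantom.radius_um + 0.0501, 0.01)
        n_grid = np.arange(lymph_phantom.n_cell - 5e-4,
                           lymph_phantom.n_cell + 5.01e-4, 1e-4)
        sse = np.array([[sphere_model_sse(lymph_phase, interior, config,
                                          x0, y0, r, n)
                         for n in n_grid] for r in r_grid])
        ir, in_ = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(m.radius_um - r_grid[ir]) <= 0.01 + 1e-9
        assert abs(m.n_cell - n_grid[in_]) <= 1e-4 + 1e-12

    def test_mean_volume_unbiased_under_phase_noise(self, config, rng):
        # 0.05 rad additive phase noise over 150 renders of one phantom:
        # mean recovered V within 1% of the closed-form truth
        ph = center_phantom(CellPhantom((0, 0), 3.675, 1.3497), config)
        truth = render_phase_image(ph, config)
        masks = segment_cells(truth)
        vols = []
        for _ in range(150):
            noisy = PhaseImage(truth.phase + rng.normal(0, 0.05,
                                                        truth.phase.shape),
                               config.pixel_scale_um)
            m = fit_sphere_model(noisy, masks[0], config)
            vols.append(m.volume_um3)
        assert np.mean(vols) == pytest.approx(ph.volume_um3, rel=0.01)

    def test_flat_phase_fails_cleanly(self, config):
        img = PhaseImage(np.zeros(config.image_shape), config.pixel_scale_um)
        mask = np.zeros(config.image_shape, bool)
        mask[50:80, 50:80] = True
        from holocyte.morpho import _contour_metrics
        a, p = _contour_metrics(mask, config.pixel_scale_um)
        cm = CellMask(mask, config.pixel_scale_um, (64.5, 64.5), a, p)
        m = fit_sphere_model(img, cm, config)
        assert "fit_failed" in m.qc_flags
        assert np.isnan(m.radius_um)

    def test_scale_equivariance(self, config):
        # halving the pixel scale changes recovered R and n_cell by < 0.2%
        results = {}
        for s in (0.1, 0.05):
            cfg = OpticalConfig(pixel_scale_um=s,
                                image_shape=(int(12.8 / s),) * 2)
            ph = center_phantom(CellPhantom((0, 0), 3.675, 1.3497), cfg)
            img = render_phase_image(ph, cfg)
            m = fit_sphere_model(img, segment_cells(img)[0], cfg)
            results[s] = (m.radius_um, m.n_cell)
        assert results[0.05][0] == pytest.approx(results[0.1][0], rel=0.002)
        assert results[0.05][1] == pytest.approx(results[0.1][1], rel=0.002)


# ------------------------------------------------------------------ QC

def _measurement(**kw):
    base = dict(n_cell=1.3497, radius_um=3.675, center_um=(6, 6),
                volume_um3=compute_volume(3.675),
                dry_mass_pg=13.2, area_um2=42.4, perimeter_um=23.1,
                ff=0.97, residual_rms=0.01, qc_flags=set(),
                label="lymphocyte")
    base.update(kw)
    return CellMeasurement(**base)


class TestQCFilter:
    def test_good_sphere_kept(self):
        kept, excluded = qc_filter([_measurement()])
        assert len(kept) == 1 and not excluded

    def test_elongated_cell_excluded_as_deformed(self):
        # 3:1 ellipse has FF ~ 0.66; with ff_min=0.7 it must be excluded
        m = _measurement(ff=0.663, label="monocyte")
        kept, excluded = qc_filter([m], QCRules(ff_min=0.7))
        assert not kept
        assert excluded[0][1] == "pmc_suspect"
        m2 = _measurement(ff=0.663)
        _, excl2 = qc_filter([m2], QCRules(ff_min=0.7))
        assert excl2[0][1] == "deformed"

    def test_attached_and_residual_and_volume_gates(self):
        ms = [
            _measurement(qc_flags={"attached"}),
            _measurement(residual_rms=0.5),
            _measurement(volume_um3=30.0),
        ]
        kept, excluded = qc_filter(ms)
        assert not kept
        assert [r for _, r in excluded] == ["attached", "high_residual",
                                            "volume_gate"]

    def test_disabled_rules_keep_everything(self):
        rules = QCRules(ff_min=0.0, residual_max_rad=np.inf,
                        volume_gates_um3={}, exclude_attached=False)
        ms = [_measurement(ff=0.2, residual_rms=9.9,
                           qc_flags={"attached"}) for _ in range(150)]
        kept, excluded = qc_filter(ms, rules)
        assert len(kept) == 150 and not excluded

    def test_partition_is_exact(self):
        ms = [_measurement(), _measurement(ff=0.1), _measurement()]
        kept, excluded = qc_filter(ms)
        assert len(kept) + len(excluded) == len(ms)
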