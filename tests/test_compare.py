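"""Plane registration and comparison metrics."""

import numpy as np
import pytest

from conedose import (
    BeamPlan,
    ComparisonConfig,
    ComparisonResult,
    ConeId,
    DosePlane,
    HorizontalPlaneSpec,
    central_profiles,
    dose_area_centroid,
    dose_plane,
    fwhm,
    masked_dose_comparison,
    register_by_centroid,
    register_by_fiducials,
    resample_to_film_grid,
    summarize,
)
from conedose.compare import displacement_sensitivity
from conedose.errors import ConfigError, DataError


def gaussian_plane(sigma_x=3.0, sigma_y=3.0, center=(0.0, 0.0), amplitude=7.0,
                   spacing=0.5, half=15.0):
    x = np.arange(-half, half + spacing / 2, spacing)
    xx, yy = np.meshgrid(x, x)
    vals = amplitude * np.exp(
        -((xx - center[0]) ** 2) / (2 * sigma_x**2)
        - ((yy - center[1]) ** 2) / (2 * sigma_y**2)
    )
    return DosePlane(values=vals, pixel_spacing_mm=(spacing, spacing),
                     origin_mm=(float(x[0]), float(x[0])))


class TestResample:
    def test_constant_plane_stays_constant(self):
        plane = DosePlane(np.full((11, 11), 3.0), (1.0, 1.0), (0.0, 0.0))
        fine = resample_to_film_grid(plane, 0.25)
        np.testing.assert_allclose(fine.values, 3.0)

    def test_bilinear_ramp_reproduced_exactly(self):
        x = np.arange(11.0)
        xx, yy = np.meshgrid(x, x)
        plane = DosePlane(2.0 * xx + 0.5 * yy, (1.0, 1.0), (0.0, 0.0))
        fine = resample_to_film_grid(plane, 0.2)
        fx, fy = np.meshgrid(fine.x_mm, fine.y_mm)
        np.testing.assert_allclose(fine.values, 2.0 * fx + 0.5 * fy, atol=1e-12)

    def test_never_exceeds_original_maximum(self, rng):
        for _ in range(10):
            vals = rng.uniform(0.0, 5.0, size=(15, 15))
            plane = DosePlane(vals, (1.0, 1.0), (0.0, 0.0))
            fine = resample_to_film_grid(plane, 0.3)
            assert fine.values.max() <= vals.max() + 1e-12

    def test_downsampling_refused(self):
        plane = DosePlane(np.ones((5, 5)), (0.5, 0.5), (0.0, 0.0))
        with pytest.raises(ConfigError):
            resample_to_film_grid(plane, 1.0)


class TestCentroid:
    def test_symmetric_plane_centred_at_origin(self):
        c = dose_area_centroid(gaussian_plane(), 0.5)
        assert abs(c[0]) < 1e-9 and abs(c[1]) < 1e-9

    def test_translation_equivariance(self):
        c = dose_area_centroid(gaussian_plane(center=(2.0, -1.5)), 0.5)
        assert c[0] == pytest.approx(2.0, abs=0.25)
        assert c[1] == pytest.approx(-1.5, abs=0.25)

    def test_matches_direct_loop_oracle(self, rng):
        vals = rng.uniform(0.0, 1.0, size=(20, 25))
        plane = DosePlane(vals, (0.7, 0.7), (-3.0, 2.0))
        got = dose_area_centroid(plane, 0.5)
        thr = 0.5 * vals.max()
        w, wx, wy = [], [], []
        for i in range(20):  # row-major, the same order the mask flattens in
            for j in range(25):
                if vals[i, j] >= thr:
                    w.append(vals[i, j])
                    wx.append(vals[i, j] * (-3.0 + 0.7 * j))
                    wy.append(vals[i, j] * (2.0 + 0.7 * i))
        sw = np.array(w).sum()
        assert got[0] == np.array(wx).sum() / sw
        assert got[1] == np.array(wy).sum() / sw

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            dose_area_centroid(DosePlane(np.zeros((5, 5)), (1, 1), (0, 0)), 0.5)


class TestCentroidRegistration:
    def test_identical_planes_give_zero_shift(self):
        plane = gaussian_plane()
        shift, reg = register_by_centroid(plane, plane)
        assert np.hypot(*shift) < 1e-9
        np.testing.assert_allclose(reg.values, plane.values, atol=1e-9)

    def test_known_shift_recovered_and_removed(self):
        plan = gaussian_plane(spacing=0.2)
        film = gaussian_plane(center=(1.0, 0.0), spacing=0.2)
        shift, reg = register_by_centroid(plan, film)
        assert shift[0] == pytest.approx(1.0, abs=0.05)
        # away from the strongest gradients the registered residual is small
        core = plan.values >= 0.8 * plan.values.max()
        resid = np.abs(reg.values - plan.values)[core] / plan.values.max()
        assert resid.max() < 0.005


class TestFiducialRegistration:
    def test_identity_for_identical_marks(self):
        marks = np.array([[0.0, 0.0], [20.0, 0.0], [20.0, 20.0], [0.0, 20.0]])
        t = register_by_fiducials(marks, marks)
        np.testing.assert_allclose(t.rotation, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)
        assert t.residual_rms_mm < 1e-12

    def test_rotation_and_shift_recovered(self):
        marks = np.array([[0.0, 0.0], [20.0, 0.0], [20.0, 20.0], [0.0, 20.0]])
        ang = np.radians(5.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = marks @ rot.T + np.array([1.5, -0.7])
        t = register_by_fiducials(marks, moved)
        assert t.angle_deg == pytest.approx(5.0, abs=1e-6)
        np.testing.assert_allclose(t.apply(marks), moved, atol=1e-6)

    def test_jittered_marks_residual_matches_jitter_scale(self, rng):
        marks = rng.uniform(-20, 20, size=(8, 2))
        jitter = 0.1
        noisy = marks + rng.normal(0.0, jitter, size=marks.shape)
        t = register_by_fiducials(marks, noisy)
        assert 0.02 < t.residual_rms_mm < 0.35

    def test_too_few_marks_rejected(self):
        with pytest.raises(DataError):
            register_by_fiducials([[0.0, 0.0]], [[1.0, 1.0]])


class TestCentralProfiles:
    def test_symmetric_plane_h_and_v_agree(self):
        h, v = central_profiles(gaussian_plane(), (0.0, 0.0))
        assert fwhm(h) == pytest.approx(fwhm(v), abs=0.5)

    def test_anisotropic_widths_match_generating_sigmas(self):
        plane = gaussian_plane(sigma_x=2.0, sigma_y=4.0, spacing=0.1)
        h, v = central_profiles(plane, (0.0, 0.0))
        k = 2.0 * np.sqrt(2.0 * np.log(2.0))
        assert fwhm(h) == pytest.approx(k * 2.0, abs=0.02)
        assert fwhm(v) == pytest.approx(k * 4.0, abs=0.02)

    def test_engine_plane_width_matches_commissioning(
        self, beam_6xfff, water_slab
    ):
        # cross-module consistency: the 15 mm cone plane at the isocenter
        # reproduces the commissioning OAR width
        cone = ConeId(15.0)
        plane = dose_plane(BeamPlan(cone=cone, mu=1000.0), beam_6xfff, water_slab,
                           HorizontalPlaneSpec(z_mm=0.0, half_extent_mm=16.0),
                           spacing_mm=0.772)
        fine = resample_to_film_grid(plane, 25.4 / 150.0)
        h, _ = central_profiles(fine, dose_area_centroid(fine, 0.5))
        ref = fwhm(beam_6xfff.oar[cone].to_profile())
        assert fwhm(h) == pytest.approx(ref, abs=0.2)

    def test_center_outside_plane_rejected(self):
        with pytest.raises(Exception):
            central_profiles(gaussian_plane(), (100.0, 0.0))


class TestMaskedComparison:
    def test_identical_planes_zero_percent(self):
        plane = gaussian_plane()
        _, _, pct = masked_dose_comparison(plane, plane)
        assert pct == 0.0

    def test_uniform_plane_channel_average(self):
        # plan 7.6 Gy vs red 7.2 / green 7.4: the red/green mean of 7.3 Gy
        # is 3.9% low after one-decimal rounding
        ones = np.ones((10, 10))
        plan = DosePlane(7.6 * ones, (1, 1), (0, 0))
        red = DosePlane(7.2 * ones, (1, 1), (0, 0))
        green = DosePlane(7.4 * ones, (1, 1), (0, 0))
        _, _, pct_r = masked_dose_comparison(plan, red)
        _, _, pct_g = masked_dose_comparison(plan, green)
        assert round((pct_r + pct_g) / 2.0, 1) == -3.9

    def test_scaled_film_gives_scaling_percent(self):
        plane = gaussian_plane()
        film = DosePlane(1.05 * plane.values, plane.pixel_spacing_mm,
                         plane.origin_mm)
        _, _, pct = masked_dose_comparison(plane, film)
        assert pct == pytest.approx(5.0, abs=1e-9)

    def test_mask_from_plan_only(self, rng):
        plan = gaussian_plane()
        film_vals = plan.values * 1.02
        mask = plan.values >= 0.8 * plan.values.max()
        _, _, pct_before = masked_dose_comparison(
            plan, DosePlane(film_vals, plan.pixel_spacing_mm, plan.origin_mm)
        )
        scrambled = film_vals.copy()
        outside = ~mask
        vals = scrambled[outside]
        scrambled[outside] = rng.permutation(vals)
        _, _, pct_after = masked_dose_comparison(
            plan, DosePlane(scrambled, plan.pixel_spacing_mm, plan.origin_mm)
        )
        assert pct_after == pct_before

    def test_empty_mask_impossible_with_valid_planes(self):
        with pytest.raises(DataError):
            masked_dose_comparison(
                DosePlane(np.zeros((5, 5)), (1, 1), (0, 0)),
                DosePlane(np.zeros((5, 5)), (1, 1), (0, 0)),
            )


class TestDisplacementSensitivity:
    def test_small_field_sensitive_to_subpixel_shift(self):
        # a 4 mm-wide flat-top field loses several percent of its 80%-mask
        # mean under a single-voxel (0.77 mm) displacement
        x = np.arange(-8.0, 8.01, 25.4 / 150.0)
        from scipy.special import erf

        prof = 0.5 * (erf((1.9 - np.abs(x)) / 1.0) + erf((1.9 + np.abs(x)) / 1.0))
        vals = 7.5 * np.outer(prof, prof) / prof.max() ** 2
        plane = DosePlane(vals, (25.4 / 150,) * 2, (float(x[0]), float(x[0])))
        pct = displacement_sensitivity(plane, (0.0, 0.772))
        assert abs(pct) > 2.0


def _result(energy, pct_rg, fwhm_plan=10.0, fwhm_meas=10.1):
    return ComparisonResult(
        energy=energy, cone=ConeId(10.0), label="10 cm",
        fwhm_plan_h_mm=fwhm_plan, fwhm_meas_h_mm={"red": fwhm_meas},
        mean80_plan_gy=7.0, mean80_meas_gy={"red": 7.0, "green": 7.0},
        pct_diff={"red": pct_rg, "green": pct_rg}, pct_diff_rg=pct_rg,
    )


class TestSummarize:
    def test_single_result_min_equals_max(self):
        s = summarize([_result("6xFFF", -1.2)])
        assert s.min_pct_diff_rg == s.max_pct_diff_rg == -1.2

    def test_permutation_invariant(self):
        results = [_result("6xFFF", p, fwhm_meas=10.0 + p / 10.0)
                   for p in (-3.0, -1.0, 0.5, 2.0)]
        s1 = summarize(results)
        s2 = summarize(list(reversed(results)))
        assert s1 == s2

    def test_empty_list_rejected(self):
        with pytest.raises(DataError):
            summarize([])

    def test_rounding_to_reporting_precision(self):
        s = summarize([_result("6xFFF", 7.345)])
        assert s.max_pct_diff_rg == 7.3
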