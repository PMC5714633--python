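"""Dose engine: radiological depth, five-factor point dose, planes, arcs."""

import numpy as np
import pytest

from conedose import (
    ArcPlan,
    BeamPlan,
    ConeId,
    CylinderPhantom,
    DepthDoseCurve,
    HorizontalPlaneSpec,
    OffAxisTable,
    OutputFactorTable,
    SlabPhantom,
    arc_dose_plane,
    dose_per_mu,
    dose_plane,
    dose_point,
    fwhm,
    mu_for_dose,
    radiological_depth,
    resolve_mu,
)
from conedose.commissioning import BeamCommissioning
from conedose.compare import central_profiles, dose_area_centroid
from conedose.engine import source_position
from conedose.errors import ConfigError, GeometryError, PrescriptionError


def brute_force_radiological_depth(phantom, source, target, step=0.01):
    """Independent oracle: fine-step numerical integration of density."""
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    length = np.linalg.norm(target - source)
    n = int(np.ceil(length / step))
    ts = (np.arange(n) + 0.5) / n
    pts = source + np.outer(ts, target - source)
    if isinstance(phantom, SlabPhantom):
        z = phantom.surface_z_mm - pts[:, 2]
        rho = np.zeros(len(pts))
        lo = 0.0
        for thickness, density in phantom.slabs:
            rho[(z > lo) & (z <= lo + thickness)] = density
            lo += thickness
    else:
        cx, cz = phantom.center_xz_mm
        inside = (pts[:, 0] - cx) ** 2 + (pts[:, 2] - cz) ** 2 <= phantom.radius_mm**2
        rho = np.where(inside, phantom.density, 0.0)
    return float(rho.sum() * length / n)


class TestRadiologicalDepth:
    def test_water_slab_equals_geometric_depth(self, water_slab):
        src = source_position(0.0)
        assert radiological_depth(water_slab, src, (0.0, 0.0, 0.0)) == \
            pytest.approx(100.0, abs=1e-9)

    def test_half_density_slab(self):
        phantom = SlabPhantom(slabs=[(50.0, 0.5), (50.0, 1.0)], surface_z_mm=100.0)
        src = source_position(0.0)
        assert radiological_depth(phantom, src, (0.0, 0.0, 0.0)) == \
            pytest.approx(75.0, abs=1e-9)

    def test_oblique_ray_matches_fine_integrator(self):
        phantom = SlabPhantom(
            slabs=[(30.0, 0.3), (40.0, 1.2), (60.0, 0.9)], surface_z_mm=60.0
        )
        src = source_position(20.0)  # oblique entry
        target = (7.0, 5.0, -40.0)
        fast = radiological_depth(phantom, src, target)
        slow = brute_force_radiological_depth(phantom, src, target)
        assert fast == pytest.approx(slow, abs=0.01)

    def test_cylinder_matches_fine_integrator(self):
        phantom = CylinderPhantom(radius_mm=38.0, density=1.05)
        src = source_position(178.0)
        target = (4.0, -6.0, 10.0)
        fast = radiological_depth(phantom, src, target)
        slow = brute_force_radiological_depth(phantom, src, target)
        assert fast == pytest.approx(slow, abs=0.01)

    def test_target_outside_phantom_rejected(self, water_slab):
        with pytest.raises(GeometryError):
            radiological_depth(water_slab, source_position(0.0), (0.0, 0.0, 150.0))


def oracle_slab_depth(phantom, src, p):
    """Independently coded analytic slab-stack radiological depth."""
    src = np.asarray(src, float)
    p = np.asarray(p, float)
    direction = p - src
    length = float(np.linalg.norm(direction))
    total = 0.0
    z_top = phantom.surface_z_mm
    for thickness, density in phantom.slabs:
        z_bot = z_top - thickness
        t_top = (z_top - src[2]) / direction[2]
        t_bot = (z_bot - src[2]) / direction[2]
        t_lo = min(max(t_top, 0.0), 1.0)
        t_hi = min(max(t_bot, 0.0), 1.0)
        total += density * abs(t_hi - t_lo) * length
        z_top = z_bot
    return total


def five_factor_oracle(plan, beam, phantom, point):
    """Independently coded product of the five dose factors."""
    src = source_position(plan.gantry_deg, plan.sad_mm)
    iso = np.asarray(plan.isocenter_mm, float)
    u = iso - src
    u = u / np.sqrt((u**2).sum())
    v = np.asarray(point, float) - src
    spd = float(v @ u)
    r = float(np.sqrt(max((v @ v) - spd**2, 0.0)))
    d = oracle_slab_depth(phantom, src, point)
    tab = beam.tmr(plan.cone)
    tmr = float(np.interp(d, tab.depths_mm, tab.tmr))
    oar_tab = beam.oar[plan.cone]
    r_meas = r * (oar_tab.measurement_ssd_mm + oar_tab.measurement_depth_mm) / spd
    oar = float(np.interp(r_meas, oar_tab.radii_mm, oar_tab.oar))
    if r_meas > oar_tab.radii_mm[-1]:
        oar = 0.0
    cref = beam.calibration_output_ref_cgy_per_mu / 100.0
    return cref * beam.output_factors[plan.cone] * tmr * oar * (plan.sad_mm / spd) ** 2


class TestDosePoint:
    def test_matches_five_factor_oracle_on_random_geometries(
        self, beam_6xfff, water_slab, rng
    ):
        cones = beam_6xfff.cones
        checked = 0
        for _ in range(100):
            cone = cones[rng.integers(len(cones))]
            plan = BeamPlan(cone=cone, gantry_deg=float(rng.uniform(-20, 20)), mu=1.0)
            point = (
                float(rng.uniform(-6, 6)),
                float(rng.uniform(-6, 6)),
                float(rng.uniform(-80, 80)),
            )
            expected = five_factor_oracle(plan, beam_6xfff, water_slab, point)
            got = dose_point(plan, beam_6xfff, water_slab, point)
            assert got == pytest.approx(expected, rel=1e-12)
            checked += 1
        assert checked == 100

    def test_reference_geometry_dose_per_mu_is_cref_times_st(self, beam_6xfff):
        # isocenter at the cone's dmax depth, SPD = SAD: TMR, OAR and the
        # inverse-square factor are all unity, so dose/MU = C_ref * St —
        # 0.689 * 0.631 cGy for the 4 mm cone
        for cone in (ConeId(4.0), ConeId(15.0)):
            phantom = SlabPhantom(slabs=[(200.0, 1.0)],
                                  surface_z_mm=beam_6xfff.dmax_mm[cone])
            dpm = float(dose_per_mu(BeamPlan(cone=cone), beam_6xfff, phantom,
                                    (0.0, 0.0, 0.0))[0])
            expected = 0.631 / 100.0 * beam_6xfff.output_factors[cone]
            assert dpm == pytest.approx(expected, rel=1e-9)
        assert beam_6xfff.output_factors[ConeId(4.0)] == 0.689

    def test_far_off_axis_dose_is_negligible(self, beam_6xfff, water_slab):
        cone = ConeId(4.0)
        plan = BeamPlan(cone=cone, mu=100.0)
        on_axis = dose_point(plan, beam_6xfff, water_slab, (0, 0, 0))
        off = dose_point(plan, beam_6xfff, water_slab, (3 * cone.radius_mm, 0, 0))
        assert off < 0.05 * on_axis

    def test_linear_in_mu(self, beam_6xfff, water_slab, cone75):
        p1 = BeamPlan(cone=cone75, mu=100.0)
        p2 = BeamPlan(cone=cone75, mu=200.0)
        pt = (1.0, -2.0, 30.0)
        assert dose_point(p2, beam_6xfff, water_slab, pt) == pytest.approx(
            2.0 * dose_point(p1, beam_6xfff, water_slab, pt), rel=1e-15
        )

    def test_inverse_square_exact_with_frozen_tmr_and_oar(self):
        # constant TMR (flat PDD) and on-axis points: dose scales exactly as
        # (SAD/SPD)^2 between two depths
        cone = ConeId(7.5)
        d = np.arange(0.0, 301.0, 5.0)
        # PDD that is pure inverse-square fall-off converts to TMR == 1
        flat = DepthDoseCurve(depths_mm=d,
                              pdd_percent=100.0 * (1000.0 / (1000.0 + d)) ** 2,
                              dmax_mm=0.0, ssd_mm=1000.0)
        r = np.arange(0.0, 30.1, 0.5)
        oar = np.exp(-((r / 6.0) ** 8))  # flat top, fast fall-off
        beam = BeamCommissioning(
            energy_label="6xFFF",
            calibration_output_ref_cgy_per_mu=0.631,
            dmax_ref_mm=13.0,
            output_factors=OutputFactorTable({cone: 0.830}),
            pdd={cone: flat},
            oar={cone: OffAxisTable(radii_mm=r, oar=oar, cone=cone)},
            dmax_mm={cone: 0.0},
        )
        phantom = SlabPhantom(slabs=[(300.0, 1.0)], surface_z_mm=100.0)
        plan = BeamPlan(cone=cone, mu=100.0)
        near = dose_point(plan, beam, phantom, (0, 0, 0))  # SPD 1000
        far = dose_point(plan, beam, phantom, (0, 0, -100.0))  # SPD 1100
        assert far / near == pytest.approx((1000.0 / 1100.0) ** 2, rel=1e-12)


class TestMuForDose:
    def test_simple_quotient(self, beam_6xfff, water_slab, cone75):
        plan = BeamPlan(cone=cone75, prescription=(7.0, (0.0, 0.0, 0.0)))
        mu = mu_for_dose(plan, beam_6xfff, water_slab)
        dpm = float(dose_per_mu(plan, beam_6xfff, water_slab, (0.0, 0.0, 0.0))[0])
        assert mu == pytest.approx(7.0 / dpm, rel=1e-15)

    def test_round_trip_reproduces_prescription(self, beam_6xfff, water_slab, cone75):
        plan = resolve_mu(
            BeamPlan(cone=cone75, prescription=(7.0, (0.0, 0.0, 0.0))),
            beam_6xfff, water_slab,
        )
        assert dose_point(plan, beam_6xfff, water_slab, (0, 0, 0)) == \
            pytest.approx(7.0, rel=1e-9)

    def test_off_beam_prescription_rejected(self, beam_6xfff, water_slab):
        plan = BeamPlan(cone=ConeId(4.0), prescription=(7.0, (50.0, 0.0, 0.0)))
        with pytest.raises(PrescriptionError):
            mu_for_dose(plan, beam_6xfff, water_slab)


class TestDosePlane:
    def test_maximum_on_central_axis_at_gantry_zero(
        self, beam_6xfff, water_slab, cone75
    ):
        plan = BeamPlan(cone=cone75, mu=1000.0)
        plane = dose_plane(plan, beam_6xfff, water_slab,
                           HorizontalPlaneSpec(z_mm=0.0, half_extent_mm=12.0))
        iy, ix = np.unravel_index(np.argmax(plane.values), plane.shape)
        assert abs(plane.x_mm[ix]) < 1e-9 and abs(plane.y_mm[iy]) < 1e-9

    def test_plane_fwhm_matches_commissioning_oar_fwhm(self, beam_6xfff, water_slab):
        # film plane at the isocenter: source-to-plane distance is the SAD,
        # so the profile width equals the commissioning OAR width
        for cone in (ConeId(4.0), ConeId(15.0)):
            plan = BeamPlan(cone=cone, mu=1000.0)
            plane = dose_plane(plan, beam_6xfff, water_slab,
                               HorizontalPlaneSpec(z_mm=0.0, half_extent_mm=16.0),
                               spacing_mm=0.25)
            h, v = central_profiles(plane, (0.0, 0.0))
            ref = fwhm(beam_6xfff.oar[cone].to_profile())
            assert fwhm(h) == pytest.approx(ref, abs=0.2)
            assert fwhm(v) == pytest.approx(ref, abs=0.2)

    def test_grid_refinement_leaves_profile_unchanged(
        self, beam_6xfff, water_slab, cone75
    ):
        plan = BeamPlan(cone=cone75, mu=1000.0)
        spec = HorizontalPlaneSpec(z_mm=0.0, half_extent_mm=12.0)
        coarse = dose_plane(plan, beam_6xfff, water_slab, spec, spacing_mm=0.8)
        fine = dose_plane(plan, beam_6xfff, water_slab, spec, spacing_mm=0.4)
        hc, _ = central_profiles(coarse, (0.0, 0.0))
        hf, _ = central_profiles(fine, (0.0, 0.0))
        assert fwhm(hf) == pytest.approx(fwhm(hc), rel=0.005)
        # point evaluation is deterministic: shared grid nodes agree exactly
        np.testing.assert_allclose(fine.values[::2, ::2], coarse.values, rtol=1e-15)

    def test_plane_outside_phantom_rejected(self, beam_6xfff, water_slab, cone75):
        plan = BeamPlan(cone=cone75, mu=100.0)
        with pytest.raises(GeometryError):
            dose_plane(plan, beam_6xfff, water_slab,
                       HorizontalPlaneSpec(z_mm=150.0, half_extent_mm=10.0))


class TestArc:
    def _arc(self, cone, **kw):
        base = dict(cone=cone, start_deg=175.0, stop_deg=185.0,
                    direction="CCW", segment_step_deg=1.0, mu=1000.0)
        base.update(kw)
        return ArcPlan(**base)

    def test_single_segment_arc_equals_static_midangle(self, beam_6xfff, cone75):
        cyl = CylinderPhantom(radius_mm=38.0)
        spec = HorizontalPlaneSpec(z_mm=0.0, half_extent_mm=10.0)
        arc = self._arc(cone75, start_deg=179.0, stop_deg=181.0,
                        segment_step_deg=2.0)
        static = BeamPlan(cone=cone75, gantry_deg=180.0, mu=1000.0)
        np.testing.assert_allclose(
            arc_dose_plane(arc, beam_6xfff, cyl, spec).values,
            dose_plane(static, beam_6xfff, cyl, spec).values,
            rtol=1e-12,
        )

    def test_direction_does_not_change_dose(self, beam_6xfff, cone75):
        cyl = CylinderPhantom(radius_mm=38.0)
        spec = HorizontalPlaneSpec(z_mm=0.0, half_extent_mm=10.0)
        ccw = arc_dose_plane(self._arc(cone75), beam_6xfff, cyl, spec)
        cw = arc_dose_plane(self._arc(cone75, direction="CW"), beam_6xfff, cyl, spec)
        np.testing.assert_array_equal(ccw.values, cw.values)

    def test_symmetric_arc_plane_is_symmetric(self, beam_6xfff, cone75):
        cyl = CylinderPhantom(radius_mm=38.0)
        spec = HorizontalPlaneSpec(z_mm=0.0, half_extent_mm=10.0)
        plane = arc_dose_plane(self._arc(cone75), beam_6xfff, cyl, spec)
        np.testing.assert_allclose(plane.values, plane.values[:, ::-1], rtol=1e-9)

    def test_short_arc_isocenter_dose_close_to_static(self, beam_6xfff, cone75):
        cyl = CylinderPhantom(radius_mm=38.0)
        arc = self._arc(cone75)
        angles = arc.segment_angles()
        total = 0.0
        for g in angles:
            seg = BeamPlan(cone=cone75, gantry_deg=float(g), mu=arc.mu / len(angles))
            total += dose_point(seg, beam_6xfff, cyl, (0, 0, 0))
        static = dose_point(BeamPlan(cone=cone75, gantry_deg=180.0, mu=1000.0),
                            beam_6xfff, cyl, (0, 0, 0))
        assert total == pytest.approx(static, rel=0.02)

    def test_step_must_divide_span(self, cone75):
        with pytest.raises(ConfigError):
            self._arc(cone75, segment_step_deg=3.0)

    def test_span_smaller_than_step_rejected(self, cone75):
        with pytest.raises(ConfigError):
            self._arc(cone75, start_deg=180.0, stop_deg=180.5,
                      segment_step_deg=1.0)


class TestPlaneAverageDepthTrend:
    def test_mask_mean_decreases_with_depth(self, beam_6xfff, water_slab, cone75):
        # slab validation geometry: plane-average dose falls 5 -> 10 -> 15 cm
        plan = resolve_mu(
            BeamPlan(cone=cone75, prescription=(7.0, (0.0, 0.0, 0.0))),
            beam_6xfff, water_slab,
        )
        means = []
        for depth in (50.0, 100.0, 150.0):
            plane = dose_plane(plan, beam_6xfff, water_slab,
                               HorizontalPlaneSpec(z_mm=100.0 - depth,
                                                   half_extent_mm=12.0))
            mask = plane.values >= 0.8 * plane.values.max()
            means.append(plane.values[mask].mean())
        assert means[0] > means[1] > means[2]
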