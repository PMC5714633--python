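"""Circular-cone dose engine.

The dose to a point from a cone-collimated beam is the product of five
measured factors::

    D(p) = MU * C_ref * St(cone) * TMR(d_rad, cone) * OAR(r, cone, SPD)
           * (SAD / SPD)**2

where ``C_ref`` is the machine calibration output for the 10x10 reference
field at 10 cm depth / 100 cm SSD (Gy/MU), ``St`` the cone output factor
referenced to that same measurement, ``d_rad`` the radiological depth along
the source ray, ``r`` the off-axis distance in the plane perpendicular to the
central axis, and ``SPD`` the source-to-point distance measured along the
central axis.  With this convention ``C_ref * St`` is the cone dose per MU at
the cone's dmax at SPD = SAD, so the inverse-square factor is referenced to
SAD (1000 mm).  Heterogeneities are handled only in the depth dimension via
radiological depth; secondary scatter is assumed negligible at these field
sizes and is not modelled.

Machine coordinates are IEC-like: x lateral, y along the gantry rotation
axis, z up, isocenter at the origin.  At gantry 0 the source sits above the
isocenter at (0, 0, SAD) and the beam points straight down; the source moves
in the x-z plane as ``SAD * (sin g, 0, cos g)``.

Arcs are computed as a sum of static segments at the segment mid-angles,
with the monitor units split equally between segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .commissioning import BeamCommissioning, ConeId, oar_lookup
from .errors import ConfigError, GeometryError, PrescriptionError
from .planes import DosePlane

__all__ = [
    "SlabPhantom",
    "CylinderPhantom",
    "BeamPlan",
    "ArcPlan",
    "HorizontalPlaneSpec",
    "source_position",
    "radiological_depth",
    "dose_point",
    "dose_per_mu",
    "mu_for_dose",
    "arc_mu_for_dose",
    "dose_plane",
    "arc_dose_plane",
]


def source_position(gantry_deg: float, sad_mm: float = 1000.0) -> np.ndarray:
    """Source position in machine coordinates for a gantry angle."""
    g = math.radians(gantry_deg)
    return np.array([sad_mm * math.sin(g), 0.0, sad_mm * math.cos(g)])


@dataclass
class SlabPhantom:
    """Stack of horizontal slabs, listed from the top surface downward.

    ``slabs`` is a sequence of (thickness_mm, density_relative_to_water).
    The top surface is the horizontal plane z = ``surface_z_mm``; the beam
    must enter through it (source above the surface).
    """

    slabs: Sequence[tuple[float, float]]
    surface_z_mm: float = 0.0

    def __post_init__(self) -> None:
        t = np.array([s[0] for s in self.slabs], dtype=float)
        rho = np.array([s[1] for s in self.slabs], dtype=float)
        if t.size == 0 or t.sum() <= 0:
            raise GeometryError("slab phantom needs positive total thickness")
        if np.any(t <= 0) or np.any(rho < 0):
            raise GeometryError("slab thicknesses must be > 0 and densities >= 0")
        # piecewise-linear map: vertical depth -> density-weighted vertical depth
        self._z_breaks = np.concatenate([[0.0], np.cumsum(t)])
        self._w_breaks = np.concatenate([[0.0], np.cumsum(t * rho)])

    @property
    def total_thickness_mm(self) -> float:
        return float(self._z_breaks[-1])

    def radiological_depth(self, source: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """Density-weighted path length from the top surface to each target."""
        p = np.atleast_2d(np.asarray(targets, dtype=float))
        s = np.asarray(source, dtype=float)
        dz_surface = self.surface_z_mm - p[:, 2]  # vertical depth of each target
        if np.any(dz_surface < -1e-9) or np.any(
            dz_surface > self.total_thickness_mm + 1e-9
        ):
            raise GeometryError("target outside slab phantom")
        if s[2] <= self.surface_z_mm:
            raise GeometryError("source must be above the slab surface")
        drop = s[2] - p[:, 2]  # vertical component of the full ray
        if np.any(drop <= 0):
            raise GeometryError("ray must travel downward through the slabs")
        length = np.linalg.norm(p - s, axis=1)
        obliquity = length / drop  # 1/cos(theta) per ray
        w = np.interp(np.clip(dz_surface, 0.0, None), self._z_breaks, self._w_breaks)
        return w * obliquity


@dataclass
class CylinderPhantom:
    """Homogeneous cylinder with its axis along y (the gantry rotation axis).

    Used as the water-equivalent stand-in for a cylindrical/spherical QA
    phantom holding a horizontal film plane.  The cylinder is treated as
    infinite along y.
    """

    radius_mm: float
    density: float = 1.0
    center_xz_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise GeometryError("cylinder radius must be positive")
        if self.density < 0:
            raise GeometryError("density must be non-negative")

    def radiological_depth(self, source: np.ndarray, targets: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(targets, dtype=float))
        s = np.asarray(source, dtype=float)
        cx, cz = self.center_xz_mm
        if np.any((p[:, 0] - cx) ** 2 + (p[:, 2] - cz) ** 2 > self.radius_mm**2 + 1e-6):
            raise GeometryError("target outside cylinder phantom")
        d = p - s  # ray directions, param t in [0, 1]
        a = d[:, 0] ** 2 + d[:, 2] ** 2
        b = 2.0 * ((s[0] - cx) * d[:, 0] + (s[2] - cz) * d[:, 2])
        c = (s[0] - cx) ** 2 + (s[2] - cz) ** 2 - self.radius_mm**2
        disc = b**2 - 4.0 * a * c
        if np.any(disc <= 0) or np.any(a <= 0):
            raise GeometryError("ray does not enter the cylinder")
        t_in = (-b - np.sqrt(disc)) / (2.0 * a)
        if np.any(t_in < 0) or np.any(t_in > 1):
            raise GeometryError("source must be outside the cylinder")
        length = np.linalg.norm(d, axis=1)
        return self.density * (1.0 - t_in) * length


def radiological_depth(phantom, source, target) -> float:
    """Scalar radiological depth along the ray ``source -> target``, in mm."""
    return float(phantom.radiological_depth(np.asarray(source, float),
                                            np.asarray(target, float))[0])


@dataclass
class BeamPlan:
    """A single static cone beam."""

    cone: ConeId
    gantry_deg: float = 0.0
    collimator_deg: float = 0.0  # irrelevant for a circular aperture; kept for record
    sad_mm: float = 1000.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mu: Optional[float] = None
    prescription: Optional[tuple[float, tuple[float, float, float]]] = None
    # prescription = (dose_gy, point_mm); resolved into mu by mu_for_dose

    def __post_init__(self) -> None:
        if self.mu is not None and self.mu <= 0:
            raise ConfigError("monitor units must be positive once resolved")

    def resolved_mu(self) -> float:
        if self.mu is None:
            raise ConfigError("plan MU not resolved; call mu_for_dose first")
        return self.mu


@dataclass
class ArcPlan(BeamPlan):
    """A single arc, delivered as equal-MU static segments at mid-angles."""

    start_deg: float = 175.0
    stop_deg: float = 185.0
    direction: str = "CCW"
    segment_step_deg: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.direction not in ("CW", "CCW"):
            raise ConfigError("arc direction must be 'CW' or 'CCW'")
        if self.span_deg <= 0:
            raise ConfigError("arc span must be positive")
        if self.segment_step_deg > self.span_deg:
            raise ConfigError("arc span smaller than segment step")
        n = self.span_deg / self.segment_step_deg
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("segment step must divide the arc span")

    @property
    def span_deg(self) -> float:
        return abs(self.stop_deg - self.start_deg)

    def segment_angles(self) -> np.ndarray:
        """Gantry angles of the segment midpoints (direction-independent)."""
        lo = min(self.start_deg, self.stop_deg)
        n = int(round(self.span_deg / self.segment_step_deg))
        return lo + (np.arange(n) + 0.5) * self.segment_step_deg


def dose_per_mu(
    plan: BeamPlan,
    beam: BeamCommissioning,
    phantom,
    points,
) -> np.ndarray:
    """Dose per monitor unit (Gy/MU) at one or more points.

    Vectorised core of the engine; ``points`` has shape (N, 3) or (3,).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    src = source_position(plan.gantry_deg, plan.sad_mm)
    iso = np.asarray(plan.isocenter_mm, dtype=float)
    axis = (iso - src) / np.linalg.norm(iso - src)

    v = p - src
    spd = v @ axis  # source-to-point distance along the central axis
    if np.any(spd <= 0):
        raise GeometryError("point behind the source")
    perp = v - np.outer(spd, axis)
    r = np.linalg.norm(perp, axis=1)

    d_rad = phantom.radiological_depth(src, p)
    cone = plan.cone
    tmr = beam.tmr(cone).tmr_at(d_rad)
    oar = oar_lookup(beam.oar[cone], r, sad_plane_mm=spd)
    c_ref = beam.calibration_output_ref_cgy_per_mu / 100.0  # Gy/MU
    st = beam.output_factors[cone]
    out = c_ref * st * tmr * np.asarray(oar) * (plan.sad_mm / spd) ** 2
    return out


def dose_point(plan: BeamPlan, beam: BeamCommissioning, phantom, point) -> float:
    """Absolute dose in Gy at a single point for a resolved plan."""
    mu = plan.resolved_mu()
    return float(mu * dose_per_mu(plan, beam, phantom, point)[0])


def mu_for_dose(plan: BeamPlan, beam: BeamCommissioning, phantom) -> float:
    """Monitor units needed to deliver the plan's prescription."""
    if plan.prescription is None:
        raise ConfigError("plan has no prescription to resolve")
    dose_gy, point = plan.prescription
    dpm = float(dose_per_mu(plan, beam, phantom, point)[0])
    if dpm <= 0:
        raise PrescriptionError(
            "zero dose per MU at the prescription point (off-beam or blocked)"
        )
    return dose_gy / dpm


def resolve_mu(plan: BeamPlan, beam: BeamCommissioning, phantom) -> BeamPlan:
    """Return a copy of the plan with MU resolved from its prescription."""
    if isinstance(plan, ArcPlan):
        return replace(plan, mu=arc_mu_for_dose(plan, beam, phantom))
    return replace(plan, mu=mu_for_dose(plan, beam, phantom))


@dataclass
class HorizontalPlaneSpec:
    """A horizontal (film) plane z = z_mm, sampled on a centred square grid."""

    z_mm: float
    half_extent_mm: float = 16.0
    center_xy_mm: tuple[float, float] = (0.0, 0.0)

    def grid(self, spacing_mm: float) -> tuple[np.ndarray, np.ndarray]:
        if spacing_mm <= 0:
            raise ConfigError("plane spacing must be positive")
        n = int(math.ceil(self.half_extent_mm / spacing_mm))
        offs = spacing_mm * np.arange(-n, n + 1)
        return self.center_xy_mm[0] + offs, self.center_xy_mm[1] + offs


#: Default plane sampling, mimicking a CT-voxel-sized dose export grid.
DEFAULT_PLANE_SPACING_MM = 0.772


def dose_plane(
    plan: BeamPlan,
    beam: BeamCommissioning,
    phantom,
    plane: HorizontalPlaneSpec,
    spacing_mm: float = DEFAULT_PLANE_SPACING_MM,
) -> DosePlane:
    """Evaluate the static-beam dose on a regular grid in a horizontal plane."""
    mu = plan.resolved_mu()
    x, y = plane.grid(spacing_mm)
    xx, yy = np.meshgrid(x, y)
    pts = np.column_stack(
        [xx.ravel(), yy.ravel(), np.full(xx.size, plane.z_mm)]
    )
    d = mu * dose_per_mu(plan, beam, phantom, pts)
    return DosePlane(
        values=d.reshape(yy.shape),
        pixel_spacing_mm=(spacing_mm, spacing_mm),
        origin_mm=(float(x[0]), float(y[0])),
        pose={
            "z_mm": plane.z_mm,
            "gantry_deg": plan.gantry_deg,
            "cone_mm": plan.cone.nominal_diameter_mm,
            "energy": beam.energy_label,
            "mu": mu,
        },
    )


def arc_mu_for_dose(arc: ArcPlan, beam: BeamCommissioning, phantom) -> float:
    """Total MU so that the summed arc segments deliver the prescription."""
    if arc.prescription is None:
        raise ConfigError("arc has no prescription to resolve")
    dose_gy, point = arc.prescription
    angles = arc.segment_angles()
    dpm = 0.0
    for g in angles:
        seg = BeamPlan(
            cone=arc.cone, gantry_deg=float(g), sad_mm=arc.sad_mm,
            isocenter_mm=arc.isocenter_mm,
        )
        dpm += float(dose_per_mu(seg, beam, phantom, point)[0]) / angles.size
    if dpm <= 0:
        raise PrescriptionError("zero arc dose per MU at the prescription point")
    return dose_gy / dpm


def arc_dose_plane(
    arc: ArcPlan,
    beam: BeamCommissioning,
    phantom,
    plane: HorizontalPlaneSpec,
    spacing_mm: float = DEFAULT_PLANE_SPACING_MM,
) -> DosePlane:
    """Arc dose as the sum of static planes at segment mid-angles."""
    mu = arc.resolved_mu()
    angles = arc.segment_angles()
    total = None
    for g in angles:
        seg = BeamPlan(
            cone=arc.cone, gantry_deg=float(g), sad_mm=arc.sad_mm,
            isocenter_mm=arc.isocenter_mm, mu=mu / angles.size,
        )
        part = dose_plane(seg, beam, phantom, plane, spacing_mm)
        total = part if total is None else replace_values(total, total.values + part.values)
    total.pose.update(
        {
            "arc_deg": (arc.start_deg, arc.stop_deg),
            "direction": arc.direction,
            "segments": int(angles.size),
            "mu": mu,
        }
    )
    return total


def replace_values(plane: DosePlane, values: np.ndarray) -> DosePlane:
    return DosePlane(
        values=values,
        pixel_spacing_mm=plane.pixel_spacing_mm,
        origin_mm=plane.origin_mm,
        pose=dict(plane.pose),
    )
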