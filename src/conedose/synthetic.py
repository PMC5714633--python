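"""Synthetic beam models, calibration sets and film scans with ground truth.

No public water-tank or film dataset exists for this kind of cone system, so
every pipeline input can be generated here with known ground truth, turning
the whole analysis into a parameter-recovery experiment: known dose plane ->
simulated film -> converted dose -> registered comparison.

The synthetic families are deliberately the simplest shapes with the right
qualitative features, not a model of any particular linac:

* Off-axis ratios are flat-topped error-function profiles
  ``OAR(r) = [erf((w/2 - r)/(sigma*sqrt2)) + erf((w/2 + r)/(sigma*sqrt2))] / 2``
  (normalised to 1 on axis).  At these field sizes a flattening filter has no
  visible effect, so FFF and flattened profiles share the family.  The width
  parameter ``w`` is calibrated numerically so the profile FWHM equals the
  requested nominal width.
* Depth dose is a two-exponential build-up/attenuation curve normalised to
  100 at dmax.
* Film response is a monotone quartic in dose per channel (red more
  sensitive at low dose, green with the larger dynamic range), plus additive
  Gaussian counts noise per channel, quantised to 16 bits.

Defaults reproduce the measured operating point of the reference dataset
(output factors, off-axis FWHMs, calibration outputs, dmax values).  All
randomness is driven by explicit seeds; identical seeds give identical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf

from . import reference_data as ref
from .commissioning import (
    BeamCommissioning,
    ConeId,
    DepthDoseCurve,
    OffAxisTable,
    OutputFactorTable,
)
from .engine import (
    ArcPlan,
    BeamPlan,
    CylinderPhantom,
    HorizontalPlaneSpec,
    SlabPhantom,
    arc_dose_plane,
    dose_plane,
    resolve_mu,
)
from .errors import ConfigError, DataError, RangeError
from .film import (
    CALIBRATION_DOSES_GY,
    CalibrationCurve,
    CalibrationSet,
    FilmScan,
    save_curves,
    write_film_scan,
)
from .planes import DosePlane, write_dose_plane

__all__ = [
    "BeamModelSpec",
    "FilmNoiseSpec",
    "make_beam_model",
    "default_true_curves",
    "make_calibration_set",
    "simulate_film_scan",
    "ScenarioItem",
    "SlabScenario",
    "scenario_slab_validation",
    "write_scenario",
]

#: Default effective attenuation of the synthetic PDD tail, per mm.
DEFAULT_ATTENUATION_PER_MM = {"6xFFF": 0.0075, "10xFFF": 0.0065, "6x": 0.0072}


@dataclass
class BeamModelSpec:
    """Parameters of a synthetic commissioning dataset for one energy."""

    energy_label: str = "6xFFF"
    cone_fwhm_mm: dict[ConeId, float] = None  # default: measured reference widths
    penumbra_sigma_mm: float = 0.7
    attenuation_per_mm: float = None  # default per energy
    dmax_mm: dict[ConeId, float] = None  # default: interpolated reference values
    output_factors: dict[ConeId, float] = None
    calibration_output_cgy_per_mu: float = None
    dmax_ref_mm: float = None
    max_depth_mm: float = 300.0
    oar_step_mm: float = 0.25
    oar_max_radius_mm: float = 30.0

    def __post_init__(self) -> None:
        e = self.energy_label
        if e not in ref.OUTPUT_FACTORS:
            raise ConfigError(f"unknown energy label {e!r}")
        if self.cone_fwhm_mm is None:
            self.cone_fwhm_mm = dict(zip(ref.CONES, ref.OAR_FWHM_MM[e]))
        if self.attenuation_per_mm is None:
            self.attenuation_per_mm = DEFAULT_ATTENUATION_PER_MM[e]
        if self.dmax_mm is None:
            self.dmax_mm = ref.cone_dmax_mm(e)
        if self.output_factors is None:
            self.output_factors = dict(zip(ref.CONES, ref.OUTPUT_FACTORS[e]))
        if self.calibration_output_cgy_per_mu is None:
            self.calibration_output_cgy_per_mu = ref.CALIBRATION_OUTPUT_CGY_PER_MU[e]
        if self.dmax_ref_mm is None:
            self.dmax_ref_mm = ref.DMAX_REF_MM[e]
        if self.penumbra_sigma_mm <= 0:
            raise ConfigError("penumbra sigma must be positive")
        cones = sorted(self.dmax_mm)
        dvals = [self.dmax_mm[c] for c in cones]
        if any(b < a for a, b in zip(dvals, dvals[1:])):
            raise ConfigError("dmax must not decrease with cone size")


def _erf_profile(r, w: float, sigma: float):
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((w / 2.0 - r) / s) + erf((w / 2.0 + r) / s))


def _erf_profile_fwhm(w: float, sigma: float) -> float:
    """FWHM of the normalised flat-top erf profile (continuous, exact)."""
    f0 = _erf_profile(0.0, w, sigma)
    half = lambda r: _erf_profile(r, w, sigma) - 0.5 * f0
    r_half = brentq(half, 0.0, w / 2.0 + 8.0 * sigma, xtol=1e-10)
    return 2.0 * r_half

def _calibrate_width(target_fwhm: float, sigma: float) -> float:
    """Width parameter w such that the erf profile's FWHM equals the target."""
    g = lambda w: _erf_profile_fwhm(w, sigma) - target_fwhm
    return brentq(g, max(0.2, target_fwhm - 4 * sigma), target_fwhm + 4 * sigma,
                  xtol=1e-10)


def _solve_buildup_rate(mu: float, dmax: float) -> float:
    """Build-up rate beta with argmax of exp(-mu d) - exp(-beta d) at dmax."""
    f = lambda b: np.log(b / mu) / (b - mu) - dmax
    return brentq(f, mu * 1.5, 5.0, xtol=1e-12)


def _pdd_depth_grid(dmax: float, max_depth: float) -> np.ndarray:
    fine = np.arange(0.0, 50.0 + 0.5, 1.0)
    coarse = np.arange(55.0, max_depth + 0.1, 5.0)
    grid = np.unique(np.concatenate([fine, coarse, [dmax]]))
    return grid[grid <= max_depth + 1e-9]


def make_beam_model(spec: BeamModelSpec) -> BeamCommissioning:
    """Build a full synthetic commissioning dataset from a spec."""
    cones = sorted(spec.output_factors)
    pdd: dict[ConeId, DepthDoseCurve] = {}
    oar: dict[ConeId, OffAxisTable] = {}
    for cone in cones:
        dmax = spec.dmax_mm[cone]
        mu = spec.attenuation_per_mm
        beta = _solve_buildup_rate(mu, dmax)
        depths = _pdd_depth_grid(dmax, spec.max_depth_mm)
        raw = np.exp(-mu * depths) - np.exp(-beta * depths)
        pdd[cone] = DepthDoseCurve(
            depths_mm=depths,
            pdd_percent=100.0 * raw / raw.max(),
            dmax_mm=dmax,
            ssd_mm=1000.0 - dmax,
        )
        w = _calibrate_width(spec.cone_fwhm_mm[cone], spec.penumbra_sigma_mm)
        radii = np.arange(0.0, spec.oar_max_radius_mm + 1e-9, spec.oar_step_mm)
        prof = _erf_profile(radii, w, spec.penumbra_sigma_mm)
        oar[cone] = OffAxisTable(radii_mm=radii, oar=prof / prof[0], cone=cone)
    return BeamCommissioning(
        energy_label=spec.energy_label,
        calibration_output_ref_cgy_per_mu=spec.calibration_output_cgy_per_mu,
        dmax_ref_mm=spec.dmax_ref_mm,
        output_factors=OutputFactorTable(dict(spec.output_factors)),
        pdd=pdd,
        oar=oar,
        dmax_mm=dict(spec.dmax_mm),
    )


# ---------------------------------------------------------------------------
# Film response families and simulated scans.

#: Monotone-decreasing quartic response(dose) coefficients c0..c4, counts vs Gy.
#: Red is steeper below ~2 Gy (higher low-dose sensitivity); green keeps a
#: steeper slope above ~8 Gy (larger dynamic range).
TRUE_RESPONSE_COEFFS = {
    "red": (42000.0, -9000.0, 1100.0, -70.0, 1.7),
    "green": (40000.0, -5200.0, 260.0, -8.0, 0.1),
}

#: Blue channel is carried to honour the 48-bit RGB format but not used
#: dosimetrically; the simulator fills it with this constant.
BLUE_FILL = 30000


def default_true_curves(dose_domain_gy=(0.0, 12.0)) -> dict[str, CalibrationCurve]:
    """Ground-truth response curves of the synthetic film family."""
    return {
        ch: CalibrationCurve(
            channel=ch,
            coefficients=np.asarray(c, dtype=float),
            dose_domain_gy=dose_domain_gy,
            lot="synthetic",
        )
        for ch, c in TRUE_RESPONSE_COEFFS.items()
    }


@dataclass
class FilmNoiseSpec:
    """Scanner/film variability model: additive Gaussian counts noise per
    channel plus a rigid film translation (setup error), at a given dpi."""

    sigma_counts: dict[str, float] = field(
        default_factory=lambda: {"red": 150.0, "green": 150.0}
    )
    dpi: float = 150.0
    translation_mm: tuple[float, float] = (0.0, 0.0)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma_counts.values()):
            raise ConfigError("noise sigma must be non-negative")
        if self.dpi <= 0:
            raise ConfigError("dpi must be positive")


def make_calibration_set(
    true_curves: dict[str, CalibrationCurve] | None = None,
    dose_levels_gy=CALIBRATION_DOSES_GY,
    sigma_counts: float | dict[str, float] = 0.0,
    seed: Optional[int] = None,
    replicates: int = 1,
) -> tuple[CalibrationSet, dict[str, CalibrationCurve]]:
    """Simulated calibration exposures: true response + Gaussian counts noise.

    Returns the noisy calibration set together with the ground-truth curves
    so fits can be checked for coefficient and inverse-dose recovery.
    """
    curves = true_curves if true_curves is not None else default_true_curves()
    for c in curves.values():
        lo, hi = c.dose_domain_gy
        if min(dose_levels_gy) < lo or max(dose_levels_gy) > hi:
            raise DataError("calibration doses fall outside the curve domain")
    if isinstance(sigma_counts, (int, float)):
        sigma_counts = {ch: float(sigma_counts) for ch in curves}
    rng = np.random.default_rng(seed)
    measurements = []
    for _ in range(replicates):
        for dose in dose_levels_gy:
            resp = {
                ch: float(curves[ch].response(dose))
                + rng.normal(0.0, sigma_counts.get(ch, 0.0))
                for ch in curves
            }
            measurements.append((float(dose), resp))
    return CalibrationSet(measurements=measurements, lot="synthetic"), curves


def simulate_film_scan(
    dose: DosePlane,
    curves: dict[str, CalibrationCurve],
    noise: FilmNoiseSpec | None = None,
    film_margin_mm: float = 2.0,
) -> tuple[FilmScan, dict]:
    """Forward-model a film scan of a dose plane.

    The film pixel grid (25.4/dpi pitch) is centred on the dose plane and
    inset by ``film_margin_mm`` so the applied translation never samples
    outside the plane.  Per channel: response = true_curve(dose at the
    translated position) + Gaussian counts noise, rounded to 16-bit integers.
    Doses outside a curve's domain raise: the simulator must not rely on the
    converter's clamping.

    Returns the scan and a truth record (applied shift, noise sigmas, seed).
    """
    noise = noise or FilmNoiseSpec()
    rng = np.random.default_rng(noise.seed)
    pitch = 25.4 / noise.dpi
    half_x = (dose.x_mm[-1] - dose.x_mm[0]) / 2.0 - film_margin_mm
    half_y = (dose.y_mm[-1] - dose.y_mm[0]) / 2.0 - film_margin_mm
    if half_x <= 0 or half_y <= 0:
        raise DataError("dose plane too small for the film margin")
    cx = (dose.x_mm[0] + dose.x_mm[-1]) / 2.0
    cy = (dose.y_mm[0] + dose.y_mm[-1]) / 2.0
    nx = int(np.floor(half_x / pitch))
    ny = int(np.floor(half_y / pitch))
    x = cx + pitch * np.arange(-nx, nx + 1)
    y = cy + pitch * np.arange(-ny, ny + 1)
    dx, dy = noise.translation_mm
    if max(abs(dx), abs(dy)) > film_margin_mm:
        raise DataError("translation offset exceeds the film margin")
    xx, yy = np.meshgrid(x - dx, y - dy)
    # the film is displaced by (dx, dy), so it records the dose at p - shift
    d = dose.sample(xx, yy)

    channels = []
    for ch in ("red", "green"):
        curve = curves[ch]
        lo, hi = curve.dose_domain_gy
        if d.min() < lo - 1e-9 or d.max() > hi + 1e-9:
            raise RangeError(
                f"simulated dose range [{d.min():.2f}, {d.max():.2f}] Gy exceeds "
                f"the {ch} calibration domain [{lo}, {hi}] Gy"
            )
        resp = curve.response(d)
        sigma = noise.sigma_counts.get(ch, 0.0)
        if sigma > 0:
            resp = resp + rng.normal(0.0, sigma, size=resp.shape)
        channels.append(np.clip(np.rint(resp), 0, 65535).astype(np.uint16))
    channels.append(np.full(d.shape, BLUE_FILL, dtype=np.uint16))
    scan = FilmScan(
        pixels=np.stack(channels, axis=-1),
        dpi=noise.dpi,
        lot="synthetic",
        metadata={"development_time_h": 24.0},
    )
    truth = {
        "translation_mm": (float(dx), float(dy)),
        "sigma_counts": dict(noise.sigma_counts),
        "seed": noise.seed,
        "source_pose": dict(dose.pose),
    }
    return scan, truth


# ---------------------------------------------------------------------------
# Full validation scenarios.

#: Slab validation geometry: isocenter at 100 mm depth, films at these depths.
SLAB_FILM_DEPTHS_MM = (50.0, 100.0, 150.0)
SLAB_PRESCRIPTION_GY = 7.0
ARC_PRESCRIPTION_GY = 7.5
#: Water-equivalent cylinder standing in for the spherical QA phantom.
ARC_PHANTOM_RADIUS_MM = 38.0


@dataclass
class ScenarioItem:
    """One plan plane plus its simulated replicate films."""

    kind: str  # "static" or "arc"
    energy: str
    cone: ConeId
    depth_label: str
    plan: DosePlane
    films: list[FilmScan]
    truths: list[dict]


@dataclass
class SlabScenario:
    """A full synthetic validation study with ground truth."""

    beams: dict[str, BeamCommissioning]
    true_curves: dict[str, CalibrationCurve]
    calibration: CalibrationSet
    items: list[ScenarioItem]
    seed: Optional[int]


def scenario_slab_validation(
    seed: int = 0,
    sigma_counts: float = 150.0,
    translation_sigma_mm: float = 0.3,
    calibration_sigma_counts: float = 100.0,
    energies: tuple[str, ...] = ("6xFFF", "10xFFF"),
    cones: tuple[ConeId, ...] | None = None,
    replicates: int = 2,
    include_arc: bool = True,
    plane_half_extent_mm: float = 16.0,
    plane_spacing_mm: float = 0.772,
) -> SlabScenario:
    """Generate the full validation study.

    Static part: for each energy and cone, a single vertical beam into a
    polystyrene slab stack (isocenter at 100 mm depth, 7 Gy prescribed),
    with plan planes exported at 50/100/150 mm depth and ``replicates``
    simulated films per plane.  Arc part: a 10-degree arc under a
    water-equivalent cylinder (about 7.5 Gy to isocenter), one film plane
    through the isocenter.

    Films are simulated from the exported plan planes, so with zero noise
    and zero translation the film chain is an exact inverse and the study
    measures the error introduced by noise, setup translation, 16-bit
    quantisation and registration alone.
    """
    rng = np.random.default_rng(seed)
    cones = tuple(cones if cones is not None else ref.CONES)
    beams = {e: make_beam_model(BeamModelSpec(energy_label=e)) for e in energies}
    calibration, true_curves = make_calibration_set(
        sigma_counts=calibration_sigma_counts,
        seed=int(rng.integers(2**31 - 1)),
    )
    # polystyrene slab stack: four 50 mm water-equivalent slabs
    phantom = SlabPhantom(slabs=[(50.0, 1.0)] * 4, surface_z_mm=100.0)
    items: list[ScenarioItem] = []
    for energy in energies:
        beam = beams[energy]
        for cone in cones:
            plan = resolve_mu(
                BeamPlan(cone=cone, gantry_deg=0.0,
                         prescription=(SLAB_PRESCRIPTION_GY, (0.0, 0.0, 0.0))),
                beam, phantom,
            )
            for depth in SLAB_FILM_DEPTHS_MM:
                spec = HorizontalPlaneSpec(
                    z_mm=100.0 - depth, half_extent_mm=plane_half_extent_mm
                )
                plane = dose_plane(plan, beam, phantom, spec, plane_spacing_mm)
                plane.pose["depth_mm"] = depth
                films, truths = _simulate_replicates(
                    plane, true_curves, rng, sigma_counts,
                    translation_sigma_mm, replicates,
                )
                items.append(ScenarioItem(
                    kind="static", energy=energy, cone=cone,
                    depth_label=f"{depth / 10:g} cm", plan=plane,
                    films=films, truths=truths,
                ))
            if include_arc:
                cyl = CylinderPhantom(radius_mm=ARC_PHANTOM_RADIUS_MM)
                arc = resolve_mu(
                    ArcPlan(cone=cone, start_deg=175.0, stop_deg=185.0,
                            direction="CCW", segment_step_deg=1.0,
                            prescription=(ARC_PRESCRIPTION_GY, (0.0, 0.0, 0.0))),
                    beam, cyl,
                )
                spec = HorizontalPlaneSpec(z_mm=0.0,
                                           half_extent_mm=plane_half_extent_mm)
                plane = arc_dose_plane(arc, beam, cyl, spec, plane_spacing_mm)
                films, truths = _simulate_replicates(
                    plane, true_curves, rng, sigma_counts,
                    translation_sigma_mm, replicates,
                )
                items.append(ScenarioItem(
                    kind="arc", energy=energy, cone=cone, depth_label="arc",
                    plan=plane, films=films, truths=truths,
                ))
    return SlabScenario(
        beams=beams, true_curves=true_curves, calibration=calibration,
        items=items, seed=seed,
    )


def _simulate_replicates(plane, curves, rng, sigma_counts, translation_sigma_mm,
                         replicates):
    films, truths = [], []
    for _ in range(replicates):
        shift = tuple(rng.normal(0.0, translation_sigma_mm, size=2)) \
            if translation_sigma_mm > 0 else (0.0, 0.0)
        noise = FilmNoiseSpec(
            sigma_counts={"red": sigma_counts, "green": sigma_counts},
            translation_mm=shift,
            seed=int(rng.integers(2**31 - 1)),
        )
        scan, truth = simulate_film_scan(plane, curves, noise)
        films.append(scan)
        truths.append(truth)
    return films, truths


def write_scenario(scenario: SlabScenario, out_dir) -> Path:
    """Write a scenario to disk: plane CSVs, film TIFFs, manifest and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_curves(scenario.true_curves, out / "true_curves.json")
    rows = []
    truth: dict = {"seed": scenario.seed, "items": []}
    for k, item in enumerate(scenario.items):
        stem = f"{item.kind}_{item.energy}_{item.cone}mm_{item.depth_label.replace(' ', '')}"
        plan_csv = out / f"{stem}_plan.csv"
        write_dose_plane(item.plan, plan_csv)
        film_paths = []
        for i, film in enumerate(item.films):
            p = out / f"{stem}_film{i + 1}.tif"
            write_film_scan(film, p)
            film_paths.append(p.name)
        rows.append({
            "kind": item.kind, "energy": item.energy,
            "cone_mm": item.cone.nominal_diameter_mm,
            "depth": item.depth_label, "plan": plan_csv.name,
            "film_1": film_paths[0],
            "film_2": film_paths[1] if len(film_paths) > 1 else "",
        })
        truth["items"].append({"index": k, "stem": stem, "truths": item.truths})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    cal_rows = [
        {"dose_gy": d, **{f"{ch}_counts": r for ch, r in resp.items()}}
        for d, resp in scenario.calibration.measurements
    ]
    pd.DataFrame(cal_rows).to_csv(out / "calibration.csv", index=False)
    return out
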