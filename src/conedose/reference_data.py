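"""Measured reference dataset for a clinical SRS cone system.

These are the commissioning and film-validation summary values measured for
BrainLAB circular cones (4-15 mm) on a Varian TrueBeam STx, for the 6xFFF and
10xFFF unflattened beams and the flattened 6x beam.  They serve two roles:

* defaults for the synthetic beam-model generator (output factors, off-axis
  FWHMs, calibration outputs, dmax values), so synthetic studies run at the
  clinically measured operating point; and
* fixture rows for the summary statistics: the static slab validation
  (film at 5/10/15 cm depth, 7 Gy prescribed to the 10 cm isocenter) and the
  arc validation (10 degree arc under a spherical QA phantom, ~7.5 Gy).

Doses are in Gy, lengths in mm, output in cGy/MU, exactly as quoted at
one-decimal / three-decimal printed precision.  Per-cone dmax values are only
quoted as ranges (smallest to largest cone); between those endpoints this
module interpolates linearly in cone diameter, which is the documented
assumption, not a measurement.
"""

from __future__ import annotations

import numpy as np

from .commissioning import CONE_DIAMETERS_MM, ConeId
from .compare import ComparisonResult

__all__ = [
    "CONES",
    "OUTPUT_FACTORS",
    "OAR_FWHM_MM",
    "CALIBRATION_OUTPUT_CGY_PER_MU",
    "DMAX_REF_MM",
    "CONE_DMAX_RANGE_MM",
    "cone_dmax_mm",
    "STATIC_VALIDATION",
    "ARC_VALIDATION",
    "static_validation_results",
    "arc_validation_results",
]

CONES = tuple(ConeId(d) for d in CONE_DIAMETERS_MM)

#: Cone output factors St, referenced to the 10x10 field at 10 cm depth, 100 SSD.
OUTPUT_FACTORS = {
    "6xFFF": (0.689, 0.790, 0.830, 0.871, 0.890, 0.901),
    "10xFFF": (0.566, 0.699, 0.756, 0.826, 0.864, 0.888),
    "6x": (0.631, 0.746, 0.795, 0.843, 0.866, 0.879),
}

#: FWHM of the commissioning off-axis ratio profiles, mm.
OAR_FWHM_MM = {
    "6xFFF": (3.8, 5.8, 7.2, 9.9, 12.3, 14.6),
    "10xFFF": (3.8, 5.9, 7.3, 9.9, 12.2, 14.5),
    "6x": (3.8, 5.8, 7.2, 9.9, 12.3, 14.6),
}

#: Machine output for the 10x10 reference field at 10 cm depth, 100 cm SSD.
CALIBRATION_OUTPUT_CGY_PER_MU = {"6xFFF": 0.631, "10xFFF": 0.708, "6x": 0.663}

#: dmax of the 10x10 reference field, mm.
DMAX_REF_MM = {"6xFFF": 13.0, "10xFFF": 21.0, "6x": 14.0}

#: Measured per-cone dmax endpoints (4 mm cone, 15 mm cone), mm.
CONE_DMAX_RANGE_MM = {"6xFFF": (8.0, 12.0), "10xFFF": (11.0, 18.0), "6x": (8.0, 14.0)}


def cone_dmax_mm(energy: str) -> dict[ConeId, float]:
    """Per-cone dmax, linearly interpolated in diameter between the quoted endpoints."""
    lo, hi = CONE_DMAX_RANGE_MM[energy]
    d = np.asarray(CONE_DIAMETERS_MM)
    vals = lo + (hi - lo) * (d - d[0]) / (d[-1] - d[0])
    return {cone: float(v) for cone, v in zip(CONES, vals)}


# ---------------------------------------------------------------------------
# Static slab validation summary: per energy and film depth, six cones each.
# dose_* in Gy (red/green are film channels), fwhm_* in mm (horizontal
# profiles, red channel).

STATIC_VALIDATION = {
    ("6xFFF", "5 cm"): {
        "dose_plan": (9.5, 9.4, 9.4, 9.5, 9.5, 9.5),
        "dose_red": (9.4, 9.2, 9.2, 9.4, 9.5, 9.5),
        "dose_green": (9.6, 9.3, 9.3, 9.5, 9.6, 9.6),
        "fwhm_plan": (3.5, 5.5, 6.8, 9.3, 11.6, 13.8),
        "fwhm_red": (3.6, 5.6, 6.9, 9.4, 11.7, 13.9),
    },
    ("6xFFF", "10 cm"): {
        "dose_plan": (6.4, 6.4, 6.4, 6.4, 6.5, 6.5),
        "dose_red": (6.2, 6.2, 6.3, 6.4, 6.5, 6.5),
        "dose_green": (6.4, 6.3, 6.4, 6.5, 6.6, 6.6),
        "fwhm_plan": (3.7, 5.8, 7.1, 9.9, 12.3, 14.6),
        "fwhm_red": (3.9, 6.0, 7.3, 10.0, 12.3, 14.7),
    },
    ("6xFFF", "15 cm"): {
        "dose_plan": (4.2, 4.3, 4.4, 4.4, 4.4, 4.5),
        "dose_red": (4.2, 4.2, 4.2, 4.3, 4.4, 4.4),
        "dose_green": (4.3, 4.3, 4.3, 4.4, 4.5, 4.5),
        "fwhm_plan": (3.9, 6.1, 7.5, 10.4, 12.9, 15.3),
        "fwhm_red": (4.1, 6.3, 7.7, 10.5, 13.1, 15.5),
    },
    ("10xFFF", "5 cm"): {
        "dose_plan": (8.8, 8.8, 8.8, 8.8, 8.7, 8.8),
        "dose_red": (8.7, 8.4, 8.4, 8.5, 8.5, 8.6),
        "dose_green": (8.9, 8.6, 8.6, 8.7, 8.7, 8.8),
        "fwhm_plan": (3.7, 5.6, 6.9, 9.4, 11.6, 13.8),
        "fwhm_red": (3.7, 5.6, 7.0, 9.4, 11.7, 13.9),
    },
    ("10xFFF", "10 cm"): {
        "dose_plan": (6.3, 6.4, 6.4, 6.4, 6.4, 6.4),
        "dose_red": (6.1, 6.1, 6.2, 6.2, 6.3, 6.4),
        "dose_green": (6.3, 6.2, 6.3, 6.3, 6.4, 6.6),
        "fwhm_plan": (3.8, 5.9, 7.2, 9.9, 12.3, 14.6),
        "fwhm_red": (3.9, 6.0, 7.4, 10.0, 12.3, 14.8),
    },
    ("10xFFF", "15 cm"): {
        "dose_plan": (4.5, 4.6, 4.7, 4.7, 4.7, 4.7),
        "dose_red": (4.5, 4.5, 4.6, 4.6, 4.7, 4.7),
        "dose_green": (4.6, 4.6, 4.7, 4.7, 4.8, 4.8),
        "fwhm_plan": (4.0, 6.2, 7.6, 10.4, 12.9, 15.2),
        "fwhm_red": (4.2, 6.3, 7.8, 10.5, 12.7, 15.4),
    },
}

#: Arc validation absolute-dose summary: per energy, six cones each, Gy.
ARC_VALIDATION = {
    "6xFFF": {
        "dose_plan": (7.4, 7.6, 7.7, 7.8, 7.8, 7.8),
        "dose_red": (7.1, 7.4, 7.4, 7.6, 7.7, 7.7),
        "dose_green": (7.2, 7.5, 7.5, 7.8, 7.8, 7.9),
    },
    "10xFFF": {
        "dose_plan": (7.3, 7.6, 7.6, 7.7, 7.7, 7.7),
        "dose_red": (7.2, 7.2, 7.2, 7.4, 7.5, 7.6),
        "dose_green": (7.3, 7.4, 7.4, 7.6, 7.6, 7.8),
    },
}


def _pct(meas: float, plan: float) -> float:
    return 100.0 * (meas - plan) / plan


def static_validation_results() -> list[ComparisonResult]:
    """The 36 static slab comparisons as ComparisonResult rows."""
    out = []
    for (energy, depth), row in STATIC_VALIDATION.items():
        for i, cone in enumerate(CONES):
            plan = row["dose_plan"][i]
            red = row["dose_red"][i]
            green = row["dose_green"][i]
            out.append(
                ComparisonResult(
                    energy=energy,
                    cone=cone,
                    label=depth,
                    fwhm_plan_h_mm=row["fwhm_plan"][i],
                    fwhm_meas_h_mm={"red": row["fwhm_red"][i]},
                    mean80_plan_gy=plan,
                    mean80_meas_gy={"red": red, "green": green},
                    pct_diff={"red": _pct(red, plan), "green": _pct(green, plan)},
                    pct_diff_rg=_pct((red + green) / 2.0, plan),
                )
            )
    return out


def arc_validation_results() -> list[ComparisonResult]:
    """The 12 arc comparisons (absolute dose only) as ComparisonResult rows."""
    out = []
    for energy, row in ARC_VALIDATION.items():
        for i, cone in enumerate(CONES):
            plan = row["dose_plan"][i]
            red = row["dose_red"][i]
            green = row["dose_green"][i]
            out.append(
                ComparisonResult(
                    energy=energy,
                    cone=cone,
                    label="arc",
                    mean80_plan_gy=plan,
                    mean80_meas_gy={"red": red, "green": green},
                    pct_diff={"red": _pct(red, plan), "green": _pct(green, plan)},
                    pct_diff_rg=_pct((red + green) / 2.0, plan),
                )
            )
    return out
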