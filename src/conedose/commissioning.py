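"""Beam commissioning data model for stereotactic circular cones.

A circular-collimator (cone) dose calculation is driven entirely by measured
beam data: per-cone scatter/output factors (St), percent depth-dose curves
(PDD) and off-axis ratios (OAR), plus a machine calibration output.  This
module holds those tables with their physical invariants, converts PDD to
tissue-maximum ratio (TMR), analyses profile widths (FWHM), and reads/writes
the on-disk commissioning bundle (manifest.json + CSV tables).

Units: lengths in mm, dose in Gy internally; the machine calibration output is
stored in cGy/MU because that is how it is quoted at the calibration boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ProfileError, RangeError, SchemaError

__all__ = [
    "CONE_DIAMETERS_MM",
    "ENERGY_LABELS",
    "ConeId",
    "Profile1D",
    "DepthDoseCurve",
    "TMRTable",
    "OffAxisTable",
    "OutputFactorTable",
    "BeamCommissioning",
    "fwhm",
    "pdd_to_tmr",
    "tmr_to_pdd",
    "oar_lookup",
    "fwhm_deviations",
    "read_commissioning",
    "write_commissioning",
]

log = logging.getLogger(__name__)

#: Nominal diameters of the supported cone set, in mm.
CONE_DIAMETERS_MM = (4.0, 6.0, 7.5, 10.0, 12.5, 15.0)

#: Beam energy labels the data model accepts (two unflattened, one flattened).
ENERGY_LABELS = ("6xFFF", "10xFFF", "6x")


@dataclass(frozen=True, order=True)
class ConeId:
    """Identifies a cone by its nominal aperture diameter in mm."""

    nominal_diameter_mm: float

    def __post_init__(self) -> None:
        d = float(self.nominal_diameter_mm)
        if not any(abs(d - ref) < 1e-9 for ref in CONE_DIAMETERS_MM):
            raise SchemaError(
                f"unknown cone diameter {d} mm; supported: {CONE_DIAMETERS_MM}"
            )
        object.__setattr__(self, "nominal_diameter_mm", d)

    @property
    def radius_mm(self) -> float:
        return self.nominal_diameter_mm / 2.0

    def __str__(self) -> str:  # "7.5" / "10"
        d = self.nominal_diameter_mm
        return f"{d:g}"


def _as1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise FormatError(f"{name} must be 1-D")
    if not np.all(np.isfinite(a)):
        raise FormatError(f"{name} contains non-finite values")
    return a


@dataclass
class Profile1D:
    """A 1-D dose profile sampled on a uniform, strictly increasing axis.

    ``offsets_mm`` are positions relative to some reference (usually the beam
    central axis or a plane centre); ``values`` are relative dose or Gy.
    """

    offsets_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_mm = _as1d(self.offsets_mm, "offsets_mm")
        self.values = _as1d(self.values, "values")
        if self.offsets_mm.size != self.values.size:
            raise FormatError("offsets and values differ in length")
        if self.offsets_mm.size < 5:
            raise FormatError("profile needs at least 5 samples")
        steps = np.diff(self.offsets_mm)
        if np.any(steps <= 0):
            raise FormatError("profile offsets must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise FormatError("profile offsets must be uniformly spaced")
        if self.values.max() <= 0:
            raise FormatError("profile maximum must be positive")

    @property
    def step_mm(self) -> float:
        return float(self.offsets_mm[1] - self.offsets_mm[0])


def _crossing(x0, y0, x1, y1, level) -> float:
    # linear interpolation of the level crossing between two samples
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def fwhm(profile: Profile1D) -> float:
    """Full width at half maximum of a peaked profile, in mm.

    Half-maximum crossings are located by linear interpolation between the
    bracketing samples.  On each flank the *outermost* crossing is taken,
    which makes the measure robust to flat-topped (FFF-like) profiles with
    small ripples near the half level.

    Raises :class:`ProfileError` if either flank never falls below half max.
    """
    x = profile.offsets_mm
    y = profile.values
    half = y.max() / 2.0
    imax = int(np.argmax(y))

    left = None
    for i in range(imax):  # scan from the left edge inwards
        if y[i] < half <= y[i + 1]:
            left = _crossing(x[i], y[i], x[i + 1], y[i + 1], half)
            break
    right = None
    for i in range(y.size - 1, imax, -1):  # scan from the right edge inwards
        if y[i] < half <= y[i - 1]:
            right = _crossing(x[i - 1], y[i - 1], x[i], y[i], half)
            break
    if left is None or right is None:
        raise ProfileError("profile not peaked: no half-maximum crossing on a flank")
    return float(right - left)


@dataclass
class DepthDoseCurve:
    """Central-axis percent depth dose at fixed SSD, normalised to 100 at dmax."""

    depths_mm: np.ndarray
    pdd_percent: np.ndarray
    dmax_mm: float
    ssd_mm: float

    def __post_init__(self) -> None:
        self.depths_mm = _as1d(self.depths_mm, "depths_mm")
        self.pdd_percent = _as1d(self.pdd_percent, "pdd_percent")
        if self.depths_mm.size != self.pdd_percent.size:
            raise FormatError("depth and PDD arrays differ in length")
        if np.any(np.diff(self.depths_mm) <= 0):
            raise FormatError("PDD depth axis must be strictly increasing")
        if np.any(self.pdd_percent < 0) or self.pdd_percent.max() > 100.0 + 1e-9:
            raise FormatError("PDD values must lie in [0, 100]")
        at_dmax = float(np.interp(self.dmax_mm, self.depths_mm, self.pdd_percent))
        if abs(at_dmax - 100.0) > 1e-6:
            raise FormatError(
                f"PDD at dmax={self.dmax_mm} mm is {at_dmax:.4f}, expected 100"
            )

    def pdd_at(self, depth_mm: float) -> float:
        d = np.asarray(depth_mm, dtype=float)
        if np.any(d < self.depths_mm[0]) or np.any(d > self.depths_mm[-1]):
            raise RangeError(
                f"depth {depth_mm} mm outside PDD range "
                f"[{self.depths_mm[0]}, {self.depths_mm[-1]}] mm"
            )
        return np.interp(d, self.depths_mm, self.pdd_percent)


@dataclass
class TMRTable:
    """Tissue-maximum ratio versus depth for one cone.

    TMR(dmax) = 1 by construction; beyond dmax the table must be
    non-increasing.  A small tolerance (0.5% per step, 1.005 absolute cap)
    admits the shallow plateau that converting a fixed-SSD PDD to TMR
    produces just beyond dmax: the divergence factor grows at ~0.2%/mm, so
    the true TMR peak sits ~1 mm deeper than the PDD peak.
    """

    depths_mm: np.ndarray
    tmr: np.ndarray
    cone: ConeId
    dmax_mm: float

    _PLATEAU_TOL = 5e-3

    def __post_init__(self) -> None:
        self.depths_mm = _as1d(self.depths_mm, "depths_mm")
        self.tmr = _as1d(self.tmr, "tmr")
        if np.any(np.diff(self.depths_mm) <= 0):
            raise FormatError("TMR depth axis must be strictly increasing")
        beyond = self.depths_mm >= self.dmax_mm - 1e-9
        t = self.tmr[beyond]
        if np.any(t <= 0) or np.any(t > 1.0 + self._PLATEAU_TOL):
            raise FormatError("TMR beyond dmax must lie in (0, 1]")
        if np.any(np.diff(t) > self._PLATEAU_TOL):
            raise FormatError("TMR must be non-increasing beyond dmax")
        at_dmax = float(np.interp(self.dmax_mm, self.depths_mm, self.tmr))
        if abs(at_dmax - 1.0) > 1e-9:
            raise FormatError("TMR at dmax must equal 1")

    def tmr_at(self, depth_mm) -> np.ndarray:
        d = np.asarray(depth_mm, dtype=float)
        if np.any(d < self.depths_mm[0]) or np.any(d > self.depths_mm[-1]):
            raise RangeError(
                f"depth outside TMR range "
                f"[{self.depths_mm[0]}, {self.depths_mm[-1]}] mm"
            )
        return np.interp(d, self.depths_mm, self.tmr)


def pdd_to_tmr(curve: DepthDoseCurve, cone: ConeId) -> TMRTable:
    """Convert a PDD curve to TMR by the inverse-square (Mayneord-type) factor.

    TMR(d) = PDD(d)/100 * ((SSD + d) / (SSD + dmax))**2

    No phantom-scatter-ratio correction is applied: for these tiny fields the
    algorithm treats secondary scatter as negligible, so the depth variation of
    scatter is carried entirely by the measured PDD.  The result is
    renormalised so TMR(dmax) = 1 exactly.
    """
    d = curve.depths_mm
    f = (curve.ssd_mm + d) / (curve.ssd_mm + curve.dmax_mm)
    tmr = (curve.pdd_percent / 100.0) * f**2
    tmr = tmr / np.interp(curve.dmax_mm, d, tmr)
    return TMRTable(depths_mm=d.copy(), tmr=tmr, cone=cone, dmax_mm=curve.dmax_mm)


def tmr_to_pdd(table: TMRTable, ssd_mm: float) -> DepthDoseCurve:
    """Inverse of :func:`pdd_to_tmr` (used for round-trip consistency checks)."""
    d = table.depths_mm
    f = (ssd_mm + table.dmax_mm) / (ssd_mm + d)
    pdd = 100.0 * table.tmr * f**2
    pdd = pdd * (100.0 / np.interp(table.dmax_mm, d, pdd))
    return DepthDoseCurve(
        depths_mm=d.copy(), pdd_percent=pdd, dmax_mm=table.dmax_mm, ssd_mm=ssd_mm
    )


@dataclass
class OffAxisTable:
    """Half-profile off-axis ratio OAR(r) for one cone.

    Measured at a fixed geometry (by default 925 mm SSD, 75 mm depth, i.e. a
    1000 mm source-to-plane distance); queries at other source-to-plane
    distances are rescaled by beam divergence before interpolation.
    """

    radii_mm: np.ndarray
    oar: np.ndarray
    cone: ConeId
    measurement_ssd_mm: float = 925.0
    measurement_depth_mm: float = 75.0

    def __post_init__(self) -> None:
        self.radii_mm = _as1d(self.radii_mm, "radii_mm")
        self.oar = _as1d(self.oar, "oar")
        if self.radii_mm[0] != 0.0:
            raise FormatError("OAR radii must start at 0")
        if np.any(np.diff(self.radii_mm) <= 0):
            raise FormatError("OAR radii must be strictly increasing")
        if abs(self.oar[0] - 1.0) > 1e-9:
            raise FormatError("OAR(0) must equal 1")
        if np.any(self.oar < 0):
            raise FormatError("OAR values must be non-negative")
        tail_from = 2.0 * self.cone.radius_mm + 5.0
        tail = self.oar[self.radii_mm >= tail_from]
        if tail.size and tail.max() >= 0.05:
            raise FormatError(
                f"OAR tail beyond {tail_from} mm must fall below 0.05 "
                f"(cone {self.cone})"
            )

    @property
    def measurement_spd_mm(self) -> float:
        """Source-to-plane distance of the measurement geometry."""
        return self.measurement_ssd_mm + self.measurement_depth_mm

    def to_profile(self) -> Profile1D:
        """Mirror the half profile into a full symmetric profile."""
        r = self.radii_mm
        full_x = np.concatenate([-r[:0:-1], r])
        full_y = np.concatenate([self.oar[:0:-1], self.oar])
        return Profile1D(offsets_mm=full_x, values=full_y)


def oar_lookup(table: OffAxisTable, r_mm, depth_mm=None, sad_plane_mm=None):
    """Off-axis ratio at radius ``r_mm`` in a plane at ``sad_plane_mm`` from the source.

    The query radius is projected back to the measurement plane through the
    divergent-beam scaling r_meas = r * SPD_meas / sad_plane and linearly
    interpolated.  ``depth_mm`` is accepted for interface symmetry but plays
    no role: the tables carry no depth dependence beyond the divergence
    scaling.  Radii beyond the table return 0 (off-beam) with a logged warning.
    """
    if sad_plane_mm is None:
        sad_plane_mm = table.measurement_spd_mm
    spd = np.asarray(sad_plane_mm, dtype=float)
    if np.any(spd <= 0):
        raise RangeError("source-to-plane distance must be positive")
    r = np.asarray(r_mm, dtype=float)
    r_meas = r * table.measurement_spd_mm / spd
    beyond = r_meas > table.radii_mm[-1]
    if np.any(beyond):
        log.warning(
            "OAR query beyond table (max radius %.1f mm, cone %s); returning 0",
            table.radii_mm[-1],
            table.cone,
        )
    out = np.interp(r_meas, table.radii_mm, table.oar)
    out = np.where(beyond, 0.0, out)
    return float(out) if np.isscalar(r_mm) or np.ndim(r_mm) == 0 else out


@dataclass
class OutputFactorTable:
    """Cone scatter/output factors St.

    Convention: each St is the ratio of the cone reading (at the cone's dmax,
    source-to-point distance 1000 mm) to the 10 cm x 10 cm reference field
    reading at 10 cm depth, 100 cm SSD — i.e. referenced directly to the
    machine-output measurement geometry, with no daisy-chaining.
    """

    st: dict[ConeId, float]

    def __post_init__(self) -> None:
        items = sorted(self.st.items())
        self.st = dict(items)
        vals = [v for _, v in items]
        if any(not (0.0 < v < 1.0) for v in vals):
            raise FormatError("output factors must lie in (0, 1)")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise FormatError("output factors must increase with cone diameter")

    def __getitem__(self, cone: ConeId) -> float:
        try:
            return self.st[cone]
        except KeyError:
            raise SchemaError(f"no output factor for cone {cone}") from None

    @property
    def cones(self) -> list[ConeId]:
        return list(self.st)


@dataclass
class BeamCommissioning:
    """All measured beam data for one energy.

    ``calibration_output_ref`` is the machine output for the 10x10 reference
    field at 10 cm depth, 100 cm SSD, in cGy/MU (the machine being calibrated
    to 1 cGy/MU at dmax for the 10x10 field at 100 SSD).
    """

    energy_label: str
    calibration_output_ref_cgy_per_mu: float
    dmax_ref_mm: float
    output_factors: OutputFactorTable
    pdd: dict[ConeId, DepthDoseCurve]
    oar: dict[ConeId, OffAxisTable]
    dmax_mm: dict[ConeId, float]
    _tmr_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.energy_label not in ENERGY_LABELS:
            raise SchemaError(
                f"unknown energy label {self.energy_label!r}; "
                f"expected one of {ENERGY_LABELS}"
            )
        if not (0.3 < self.calibration_output_ref_cgy_per_mu < 1.2):
            raise FormatError(
                "calibration output must lie in (0.3, 1.2) cGy/MU; got "
                f"{self.calibration_output_ref_cgy_per_mu}"
            )
        cones = set(self.output_factors.cones)
        for name, table in (("pdd", self.pdd), ("oar", self.oar),
                            ("dmax", self.dmax_mm)):
            missing = cones - set(table)
            extra = set(table) - cones
            if missing or extra:
                bad = ", ".join(str(c) for c in sorted(missing | extra))
                raise SchemaError(f"cone set mismatch in {name} table: {bad}")

    @property
    def cones(self) -> list[ConeId]:
        return self.output_factors.cones

    def tmr(self, cone: ConeId) -> TMRTable:
        """TMR table for one cone, derived (and cached) from its PDD curve."""
        if cone not in self._tmr_cache:
            self._tmr_cache[cone] = pdd_to_tmr(self.pdd[cone], cone)
        return self._tmr_cache[cone]


def fwhm_deviations(
    measured_fwhm_mm: dict[ConeId, float],
) -> dict[ConeId, float]:
    """Signed deviation of measured off-axis FWHM from nominal cone diameter."""
    return {
        cone: float(w) - cone.nominal_diameter_mm
        for cone, w in measured_fwhm_mm.items()
    }


# ---------------------------------------------------------------------------
# Bundle I/O: directory with manifest.json + CSV tables (UTF-8, dot decimal).


def write_commissioning(beam: BeamCommissioning, path) -> None:
    """Write a commissioning bundle directory for one energy."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "energy_label": beam.energy_label,
        "calibration_output_ref_cgy_per_mu": beam.calibration_output_ref_cgy_per_mu,
        "dmax_ref_mm": beam.dmax_ref_mm,
        "dmax_mm": {str(c): beam.dmax_mm[c] for c in beam.cones},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    pd.DataFrame(
        {
            "cone_mm": [c.nominal_diameter_mm for c in beam.cones],
            "st": [beam.output_factors[c] for c in beam.cones],
        }
    ).to_csv(path / "output_factors.csv", index=False)
    for cone in beam.cones:
        curve = beam.pdd[cone]
        pd.DataFrame(
            {"depth_mm": curve.depths_mm, "pdd_percent": curve.pdd_percent}
        ).to_csv(path / f"pdd_{cone}.csv", index=False)
        # PDD geometry rides in the manifest-free CSV via a sidecar-less
        # convention: ssd is recoverable as 1000 - dmax; store explicitly too.
        oar = beam.oar[cone]
        pd.DataFrame({"radius_mm": oar.radii_mm, "oar": oar.oar}).to_csv(
            path / f"oar_{cone}.csv", index=False
        )


def read_commissioning(path) -> BeamCommissioning:
    """Read a commissioning bundle directory written by :func:`write_commissioning`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    try:
        dmax_mm = {
            ConeId(float(k)): float(v) for k, v in manifest["dmax_mm"].items()
        }
        energy = manifest["energy_label"]
        cal = float(manifest["calibration_output_ref_cgy_per_mu"])
        dmax_ref = float(manifest["dmax_ref_mm"])
    except KeyError as exc:
        raise SchemaError(f"manifest missing key {exc}") from None

    of_df = pd.read_csv(path / "output_factors.csv")
    st = {
        ConeId(row.cone_mm): float(row.st) for row in of_df.itertuples()
    }
    cones = sorted(st)
    pdd: dict[ConeId, DepthDoseCurve] = {}
    oar: dict[ConeId, OffAxisTable] = {}
    for cone in cones:
        pdd_file = path / f"pdd_{cone}.csv"
        oar_file = path / f"oar_{cone}.csv"
        for f in (pdd_file, oar_file):
            if not f.exists():
                raise SchemaError(f"bundle missing table for cone {cone}: {f.name}")
        if cone not in dmax_mm:
            raise SchemaError(f"manifest dmax_mm missing cone {cone}")
        pdf = pd.read_csv(pdd_file)
        pdd[cone] = DepthDoseCurve(
            depths_mm=pdf["depth_mm"].to_numpy(),
            pdd_percent=pdf["pdd_percent"].to_numpy(),
            dmax_mm=dmax_mm[cone],
            ssd_mm=1000.0 - dmax_mm[cone],
        )
        odf = pd.read_csv(oar_file)
        oar[cone] = OffAxisTable(
            radii_mm=odf["radius_mm"].to_numpy(),
            oar=odf["oar"].to_numpy(),
            cone=cone,
        )
    return BeamCommissioning(
        energy_label=energy,
        calibration_output_ref_cgy_per_mu=cal,
        dmax_ref_mm=dmax_ref,
        output_factors=OutputFactorTable(st),
        pdd=pdd,
        oar=oar,
        dmax_mm=dmax_mm,
    )
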