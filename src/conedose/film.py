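"""Radiochromic film dosimetry: scans, calibration curves, dose conversion.

The measurement chain mirrors standard EBT3 practice: film pieces are scanned
on a flatbed scanner as uncompressed 48-bit RGB TIFF (16 bits/channel,
150 dpi), the mean red/green channel response over a central region of
interest is recorded for a series of known calibration doses, a fourth-order
polynomial *response(dose)* is least-squares fitted per channel, and film
images are converted to absolute dose by numerically inverting that
polynomial pixel by pixel.  "Response" here means raw mean channel counts —
no optical-density transform — and no smoothing is ever applied to converted
dose maps.

The red channel is the more sensitive at low dose; the green channel has the
larger dynamic range, which is why both are carried through the pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import brentq

from .errors import (
    CalibrationError,
    FormatError,
    GeometryError,
    NumericalError,
    RangeError,
)
from .planes import DosePlane

__all__ = [
    "CHANNELS",
    "FilmScan",
    "CalibrationCurve",
    "CalibrationSet",
    "read_film_scan",
    "write_film_scan",
    "roi_mean",
    "fit_calibration",
    "response_to_dose",
    "film_to_dose",
    "save_curves",
    "load_curves",
]

log = logging.getLogger(__name__)

CHANNELS = ("red", "green", "blue")
_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}

#: Dose levels of the standard calibration series, in Gy (an unirradiated
#: film provides the 0 Gy anchor).
CALIBRATION_DOSES_GY = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0)


@dataclass
class FilmScan:
    """A scanned film piece: 16-bit-per-channel RGB image with physical dpi."""

    pixels: np.ndarray  # (ny, nx, 3) uint16
    dpi: float = 150.0
    orientation_mark: str = "upper_left"
    lot: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError("film scan must be an (ny, nx, 3) RGB image")
        if px.dtype != np.uint16:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 65535:
                px = px.astype(np.uint16)
            else:
                raise FormatError("film scan must be 16 bits per channel")
        self.pixels = px
        if self.dpi <= 0:
            raise FormatError("dpi must be positive")

    @property
    def pixel_pitch_mm(self) -> float:
        return 25.4 / self.dpi

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.pixels[:, :, _CHANNEL_INDEX[name]].astype(float)
        except KeyError:
            raise FormatError(f"unknown channel {name!r}") from None


def write_film_scan(scan: FilmScan, path) -> None:
    """Write an uncompressed RGB TIFF with dpi in the resolution tags."""
    import tifffile

    tifffile.imwrite(
        Path(path),
        scan.pixels,
        photometric="rgb",
        compression=None,
        resolution=(scan.dpi, scan.dpi),
        resolutionunit="INCH",
        metadata={"lot": scan.lot, "orientation_mark": scan.orientation_mark},
    )


def read_film_scan(path, dpi_override: float | None = None) -> FilmScan:
    """Read a film TIFF, validating bit depth and extracting dpi from the tags."""
    import tifffile

    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        pixels = page.asarray()
        dpi = dpi_override
        if dpi is None:
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is None:
                raise FormatError(f"{path}: no resolution tag; pass dpi_override")
            num, den = res.value
            dpi = num / den
            if unit is not None and getattr(unit.value, "name", str(unit.value)) in (
                "CENTIMETER", "3",
            ):
                dpi *= 2.54
    if pixels.dtype != np.uint16:
        raise FormatError(f"{path}: expected 16 bits per channel, got {pixels.dtype}")
    return FilmScan(pixels=pixels, dpi=float(dpi))


def roi_mean(scan: FilmScan, roi_size_mm: float, channel: str) -> float:
    """Mean channel response over a square ROI centred on the scan.

    A pixel contributes if its centre falls inside the ROI (half-open check
    avoided: the boundary is inclusive to within floating tolerance).
    """
    img = scan.channel(channel)
    ny, nx = img.shape
    pitch = scan.pixel_pitch_mm
    if roi_size_mm <= 0:
        raise GeometryError("ROI size must be positive")
    if roi_size_mm > min(ny, nx) * pitch:
        raise GeometryError("ROI exceeds the scanned image")
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    half_px = (roi_size_mm / 2.0) / pitch
    xs = np.abs(np.arange(nx) - cx) <= half_px + 1e-9
    ys = np.abs(np.arange(ny) - cy) <= half_px + 1e-9
    return float(img[np.ix_(ys, xs)].mean())


@dataclass
class CalibrationCurve:
    """Per-channel quartic response(dose) mapping with a valid dose domain.

    ``coefficients`` are c0..c4 (ascending powers) of
    ``response = c0 + c1*D + ... + c4*D**4`` with D in Gy.  The polynomial
    must be strictly monotone over ``dose_domain_gy`` so it has a
    single-valued inverse.
    """

    channel: str
    coefficients: np.ndarray
    dose_domain_gy: tuple[float, float] = (0.0, 12.0)
    residual_rms: float = 0.0
    lot: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (5,):
            raise FormatError("calibration curve needs 5 coefficients c0..c4")
        self.coefficients = c
        lo, hi = self.dose_domain_gy
        if not hi > lo:
            raise FormatError("dose domain must be a non-empty interval")
        if not self._is_monotone():
            raise CalibrationError(
                f"{self.channel} calibration polynomial is not monotone on "
                f"[{lo}, {hi}] Gy; acquire more or better calibration points"
            )

    def _is_monotone(self, n: int = 1000) -> bool:
        lo, hi = self.dose_domain_gy
        d = np.linspace(lo, hi, n)
        slope = npoly.polyval(d, npoly.polyder(self.coefficients))
        return bool(np.all(slope > 0) or np.all(slope < 0))

    def response(self, dose_gy) -> np.ndarray:
        return npoly.polyval(np.asarray(dose_gy, dtype=float), self.coefficients)

    @property
    def slope_sign(self) -> float:
        lo, hi = self.dose_domain_gy
        return float(np.sign(self.response(hi) - self.response(lo)))

    def response_range(self) -> tuple[float, float]:
        """(min, max) attainable response over the dose domain."""
        lo, hi = self.dose_domain_gy
        r0, r1 = float(self.response(lo)), float(self.response(hi))
        return (min(r0, r1), max(r0, r1))


@dataclass
class CalibrationSet:
    """Measured (dose, mean channel response) points, replicates allowed.

    ``measurements`` maps each dose in Gy to per-channel mean ROI responses;
    multiple entries at the same dose are treated as replicates and averaged
    at fit time (the averaging is logged).  The 0 Gy entry is the
    unirradiated-film response.
    """

    measurements: list[tuple[float, dict[str, float]]]
    roi_size_mm: float = 5.0
    lot: str = ""

    def __post_init__(self) -> None:
        if not self.measurements:
            raise FormatError("empty calibration set")

    def points(self, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """Distinct doses and replicate-averaged responses for one channel."""
        by_dose: dict[float, list[float]] = {}
        for dose, resp in self.measurements:
            if channel not in resp:
                raise FormatError(f"measurement at {dose} Gy lacks channel {channel}")
            by_dose.setdefault(round(float(dose), 6), []).append(float(resp[channel]))
        doses = np.array(sorted(by_dose))
        if any(len(v) > 1 for v in by_dose.values()):
            log.info("averaging replicate calibration responses per dose level")
        responses = np.array([np.mean(by_dose[d]) for d in doses])
        diffs = np.diff(responses)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            log.warning(
                "%s-channel calibration responses are not monotone in dose", channel
            )
        return doses, responses


def fit_calibration(
    cal: CalibrationSet,
    channel: str,
    dose_domain_gy: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Least-squares quartic fit of response on dose for one channel.

    Requires at least 6 distinct dose levels including the unirradiated
    (0 Gy) film.  Fits that are non-monotone over the dose domain are
    rejected, because they have no single-valued inverse.
    """
    doses, responses = cal.points(channel)
    if doses.size < 6:
        raise CalibrationError(
            f"need >= 6 distinct dose levels for a quartic fit, got {doses.size}"
        )
    if doses.min() > 0:
        raise CalibrationError("calibration set must include the 0 Gy (unirradiated) film")
    if dose_domain_gy is None:
        dose_domain_gy = (float(doses.min()), float(doses.max()))
    lo, hi = dose_domain_gy
    if lo > doses.min() or hi < doses.max():
        raise CalibrationError("dose domain must cover all calibration doses")
    coeffs = npoly.polyfit(doses, responses, 4)
    resid = responses - npoly.polyval(doses, coeffs)
    return CalibrationCurve(
        channel=channel,
        coefficients=coeffs,
        dose_domain_gy=(lo, hi),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        lot=cal.lot,
    )


def response_to_dose(curve: CalibrationCurve, response: float) -> float:
    """Invert the calibration polynomial for a single response value.

    Uses a bracketed root find over the dose domain (tolerance 1e-4 Gy
    or better).  Responses outside the attainable range are clamped to the
    corresponding domain edge with a logged warning — saturated or dusty
    pixels should not abort a whole-film conversion.
    """
    if np.isnan(response):
        raise NumericalError("NaN film response")
    lo, hi = curve.dose_domain_gy
    rmin, rmax = curve.response_range()
    if response < rmin or response > rmax:
        r_lo, r_hi = float(curve.response(lo)), float(curve.response(hi))
        edge = lo if abs(response - r_lo) <= abs(response - r_hi) else hi
        log.warning(
            "response %.1f outside attainable range [%.1f, %.1f]; clamping to %s Gy",
            response, rmin, rmax, edge,
        )
        return float(edge)
    f = lambda d: float(curve.response(d)) - float(response)
    return float(brentq(f, lo, hi, xtol=1e-6))


def _invert_many(curve: CalibrationCurve, responses: np.ndarray) -> tuple[np.ndarray, float]:
    """Vectorised polynomial inversion: dense monotone lookup + Newton polish.

    Returns (doses, clamped_fraction).
    """
    lo, hi = curve.dose_domain_gy
    grid = np.linspace(lo, hi, 8193)
    rgrid = curve.response(grid)
    if curve.slope_sign < 0:  # np.interp needs an increasing abscissa
        rgrid = rgrid[::-1]
        ggrid = grid[::-1]
    else:
        ggrid = grid
    rmin, rmax = curve.response_range()
    clamped = (responses < rmin) | (responses > rmax)
    r = np.clip(responses, rmin, rmax)
    d = np.interp(r, rgrid, ggrid)
    deriv = npoly.polyder(curve.coefficients)
    for _ in range(2):  # Newton refinement, well-conditioned on a monotone curve
        d = d - (npoly.polyval(d, curve.coefficients) - r) / npoly.polyval(d, deriv)
        d = np.clip(d, lo, hi)
    return d, float(clamped.mean())


def film_to_dose(scan: FilmScan, curve: CalibrationCurve) -> DosePlane:
    """Convert a whole film scan to an absolute dose plane, pixel by pixel.

    No smoothing is applied; the output grid is the film pixel grid
    (25.4/dpi mm pitch, 0.1693 mm at 150 dpi), centred on the scan centre.
    The fraction of clamped (out-of-range) pixels is reported in the plane's
    ``pose`` as a QC output.
    """
    responses = scan.channel(curve.channel)
    doses, clamped_fraction = _invert_many(curve, responses.ravel())
    # clamping is routine for background pixels whose noise pushes the
    # response above the unirradiated level; it is a QC number, not a fault
    log_at = log.warning if clamped_fraction > 0.9 else log.debug
    log_at("%.2f%% of film pixels clamped to the dose domain edge",
           100 * clamped_fraction)
    values = doses.reshape(responses.shape)
    pitch = scan.pixel_pitch_mm
    ny, nx = responses.shape
    origin = (-(nx - 1) / 2.0 * pitch, -(ny - 1) / 2.0 * pitch)
    return DosePlane(
        values=values,
        pixel_spacing_mm=(pitch, pitch),
        origin_mm=origin,
        pose={
            "channel": curve.channel,
            "clamped_fraction": clamped_fraction,
            "lot": scan.lot,
        },
    )


def save_curves(curves: dict[str, CalibrationCurve], path) -> None:
    """Store calibration curves as JSON."""
    payload = {
        ch: {
            "channel": c.channel,
            "coefficients": list(c.coefficients),
            "dose_domain_gy": list(c.dose_domain_gy),
            "residual_rms": c.residual_rms,
            "lot": c.lot,
        }
        for ch, c in curves.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_curves(path) -> dict[str, CalibrationCurve]:
    payload = json.loads(Path(path).read_text())
    return {
        ch: CalibrationCurve(
            channel=spec["channel"],
            coefficients=np.asarray(spec["coefficients"], dtype=float),
            dose_domain_gy=tuple(spec["dose_domain_gy"]),
            residual_rms=float(spec.get("residual_rms", 0.0)),
            lot=spec.get("lot", ""),
        )
        for ch, spec in payload.items()
    }
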