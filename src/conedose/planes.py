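"""2-D dose plane container and I/O.

A :class:`DosePlane` is a regular 2-D grid of absorbed dose in Gy with
physical pixel spacing and an origin, both in mm.  Conventions:

* array axis 0 (rows) runs along physical y, axis 1 (columns) along x;
* ``origin_mm = (x0, y0)`` is the physical position of the centre of pixel
  ``[0, 0]``; pixel ``[i, j]`` sits at ``(x0 + j*dx, y0 + i*dy)``;
* ``pose`` is free-form metadata (depth, energy, cone, ...) carried through
  the pipeline and serialised to the JSON sidecar.

On disk a plane is a bare CSV matrix plus a JSON sidecar with the grid
geometry.  Single-frame, axis-aligned DICOM RTDOSE files can be imported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import FormatError, GeometryError

__all__ = ["DosePlane", "read_dose_plane", "write_dose_plane", "read_rtdose_plane"]


@dataclass
class DosePlane:
    values: np.ndarray  # Gy, shape (ny, nx)
    pixel_spacing_mm: tuple[float, float]  # (dy, dx)
    origin_mm: tuple[float, float]  # (x0, y0) of pixel centre [0, 0]
    pose: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("dose plane values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("dose plane contains non-finite values")
        if np.any(self.values < 0):
            raise FormatError("dose plane contains negative dose")
        dy, dx = (float(s) for s in self.pixel_spacing_mm)
        if dy <= 0 or dx <= 0:
            raise FormatError("pixel spacing must be positive")
        self.pixel_spacing_mm = (dy, dx)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_mm(self) -> np.ndarray:
        """Physical x coordinate of each column (pixel centres)."""
        x0 = self.origin_mm[0]
        return x0 + self.pixel_spacing_mm[1] * np.arange(self.shape[1])

    @property
    def y_mm(self) -> np.ndarray:
        """Physical y coordinate of each row (pixel centres)."""
        y0 = self.origin_mm[1]
        return y0 + self.pixel_spacing_mm[0] * np.arange(self.shape[0])

    def interpolator(self, fill_value: float = 0.0) -> RegularGridInterpolator:
        """Bilinear interpolator f((y, x)) -> Gy over the plane extent."""
        return RegularGridInterpolator(
            (self.y_mm, self.x_mm),
            self.values,
            method="linear",
            bounds_error=False,
            fill_value=fill_value,
        )

    def sample(self, x_mm, y_mm, fill_value: float = 0.0) -> np.ndarray:
        """Bilinear dose sample at physical positions (broadcast arrays)."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        pts = np.stack(np.broadcast_arrays(y, x), axis=-1)
        return self.interpolator(fill_value)(pts)

    def shifted(self, shift_mm: tuple[float, float]) -> "DosePlane":
        """The same dose field translated by ``shift_mm = (dx, dy)``.

        Implemented by moving the origin; no resampling is involved.
        """
        dx, dy = shift_mm
        return DosePlane(
            values=self.values.copy(),
            pixel_spacing_mm=self.pixel_spacing_mm,
            origin_mm=(self.origin_mm[0] + dx, self.origin_mm[1] + dy),
            pose=dict(self.pose),
        )


def write_dose_plane(plane: DosePlane, csv_path) -> None:
    """Write a plane as CSV matrix + ``<name>.json`` sidecar."""
    csv_path = Path(csv_path)
    np.savetxt(csv_path, plane.values, delimiter=",", fmt="%.8g")
    sidecar = {
        "spacing_mm": list(plane.pixel_spacing_mm),
        "origin_mm": list(plane.origin_mm),
        "units": "Gy",
        "pose": plane.pose,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_dose_plane(csv_path) -> DosePlane:
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for {csv_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("units", "Gy") != "Gy":
        raise FormatError("dose plane sidecar units must be Gy")
    values = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    return DosePlane(
        values=values,
        pixel_spacing_mm=tuple(sidecar["spacing_mm"]),
        origin_mm=tuple(sidecar["origin_mm"]),
        pose=sidecar.get("pose", {}),
    )


def read_rtdose_plane(path) -> DosePlane:
    """Import a single-frame, axis-aligned DICOM RTDOSE file as a plane.

    Only the simple export geometry is supported: one frame, identity-like
    image orientation, dose in Gy after ``DoseGridScaling``.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError("not an RTDOSE file")
    nframes = int(getattr(ds, "NumberOfFrames", 1))
    if nframes != 1:
        raise GeometryError("only single-frame RTDOSE planes are supported")
    orient = [float(v) for v in ds.ImageOrientationPatient]
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0]):
        raise GeometryError("only axis-aligned RTDOSE planes are supported")
    scaling = float(ds.DoseGridScaling)
    values = ds.pixel_array.astype(float) * scaling
    dy, dx = (float(v) for v in ds.PixelSpacing)  # row spacing, column spacing
    x0, y0 = float(ds.ImagePositionPatient[0]), float(ds.ImagePositionPatient[1])
    return DosePlane(
        values=values,
        pixel_spacing_mm=(dy, dx),
        origin_mm=(x0, y0),
        pose={"source": "rtdose", "units_in": getattr(ds, "DoseUnits", "GY")},
    )
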