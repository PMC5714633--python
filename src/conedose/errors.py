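"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.  Library code raises the most specific subclass.
"""


class ConeDoseError(Exception):
    """Base class for all package errors."""


class ConfigError(ConeDoseError):
    """Invalid run configuration (unknown keys, missing paths, bad options)."""


class DataError(ConeDoseError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A commissioning bundle or manifest is structurally incomplete."""


class FormatError(DataError):
    """A file parsed but violated a format invariant (e.g. non-monotone axis)."""


class GeometryError(DataError):
    """A point, plane or ROI lies outside the supported geometry."""


class RangeError(DataError):
    """A lookup outside the commissioned data range (no extrapolation)."""


class ProfileError(DataError):
    """A profile is not peaked / has no half-maximum crossings."""


class NumericalError(ConeDoseError):
    """A numerical procedure failed to produce a usable result."""


class CalibrationError(NumericalError):
    """Calibration fit rejected (e.g. non-monotone fitted response)."""


class PrescriptionError(NumericalError):
    """Monitor units cannot be resolved (zero dose per MU at the point)."""
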