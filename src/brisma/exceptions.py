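"""Exception hierarchy.

Every error raised by the package derives from :class:`BrismaError` so
pipeline drivers can catch per-sample failures without masking bugs.
"""


class BrismaError(Exception):
    """Base class for all package errors."""


class SpectrumParseError(BrismaError):
    """A spectrum file contains non-numeric or malformed rows."""


class SpectrumSizeError(BrismaError):
    """A spectrum has fewer points than the configured minimum."""


class SpectrumAxisError(BrismaError):
    """A spectral axis is not strictly increasing (duplicates etc.)."""


class ManifestError(BrismaError):
    """A sample manifest fails validation (enums, missing files)."""


class PeakDetectionError(BrismaError):
    """No peak of sufficient prominence on one side of the elastic line."""


class CalibrationError(BrismaError):
    """Axis offset beyond plausible drift, or an impossible calibration."""


class FitError(BrismaError):
    """Nonlinear fit failed to converge or was given degenerate data."""


class ConfigurationError(BrismaError):
    """Inconsistent processing configuration (windows, anchors, spans)."""


class RangeError(BrismaError):
    """Requested axis range falls outside the data span."""


class GridError(BrismaError):
    """Two spectra do not share a common axis where one is required."""


class OptimizationError(BrismaError):
    """Normalization-factor search failed to improve from any start."""


class RatioError(BrismaError):
    """CH/OH ratio undefined (OH band isolation failed)."""


class ModelViolationError(BrismaError):
    """Composition outside the range the biphasic model can represent."""


class IllConditionedError(BrismaError):
    """Mixture inversion requested with a vanishing volume fraction."""


class RegionError(BrismaError):
    """Image region operation on an empty mask or label image."""


class ZoneAssignmentError(BrismaError):
    """A nucleus centroid falls outside the spheroid mask."""


class PackingError(BrismaError):
    """Synthetic nuclei could not be placed without overlap."""


class SampleSizeError(BrismaError):
    """Too few observations per group for the requested comparison."""
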