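"""Exception hierarchy for the ergflick package."""


class ErgflickError(Exception):
    """Base class for all package-specific errors."""


class ProtocolError(ErgflickError, ValueError):
    """Invalid stimulus protocol specification."""


class DomainError(ErgflickError, ValueError):
    """Argument outside its physical domain (negative intensity, distance, ...)."""


class CoverageError(ErgflickError, ValueError):
    """A spectrum does not cover the requested integration range."""


class AliasingError(ErgflickError, ValueError):
    """Sampling rate too low for the requested stimulus frequency."""


class ConfigError(ErgflickError, ValueError):
    """Invalid configuration (bad filter corners, unknown keys, missing sections)."""


class DataError(ErgflickError, ValueError):
    """Malformed input data (non-finite samples, wrong shapes)."""


class MeasurementError(ErgflickError, ValueError):
    """Spectral response measurement cannot be carried out (too few noise bins...)."""


class FitError(ErgflickError, ValueError):
    """Intensity-response line fit failed (too few selectable points)."""


class EstimationError(ErgflickError, ValueError):
    """Threshold or fusion-frequency estimation failed (non-positive slope...)."""


class DesignError(ErgflickError, ValueError):
    """Statistical design invalid for the requested test."""


class ModelError(ErgflickError, ValueError):
    """Mixed-model fit failed (singular design, too few subjects)."""


class IntegrityError(ErgflickError, IOError):
    """Stored dataset failed its integrity check."""


class DatasetVersionError(ErgflickError, IOError):
    """Stored dataset was written by an incompatible format version."""


class UnusableRecordingError(ErgflickError, ValueError):
    """Recording rejected by quality control (excess masked samples)."""
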