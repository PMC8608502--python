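"""Exception hierarchy for the CAD pipeline.

All pipeline errors derive from :class:`LungCADError` so callers can catch one
base class; input/config problems additionally derive from ``ValueError``.
"""


class LungCADError(Exception):
    """Base class for all lungcad errors."""


class InputError(LungCADError, ValueError):
    """Unreadable, malformed, or inconsistent input data."""


class ConfigError(LungCADError, ValueError):
    """Invalid configuration value (e.g. a filter radius below one pixel)."""


class ValidationError(LungCADError, ValueError):
    """A domain object violates one of its invariants."""


class DegenerateInputError(LungCADError, ValueError):
    """Input is technically readable but carries no usable signal
    (e.g. a constant-intensity volume offered for thresholding)."""


class ConvergenceError(LungCADError, RuntimeError):
    """Iterative procedure failed to converge within its iteration budget."""

    def __init__(self, message: str, last_value: float | None = None):
        super().__init__(message)
        self.last_value = last_value


class SegmentationError(LungCADError, RuntimeError):
    """Lung segmentation produced no acceptable lung component."""


class FeatureExtractionError(LungCADError, RuntimeError):
    """Candidate region was too degenerate to featurize."""
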