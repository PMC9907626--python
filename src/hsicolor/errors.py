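"""Exception hierarchy.

All package errors derive from :class:`HsiColorError` so callers can catch
one base class; structural problems (shape mismatches, bad configuration)
additionally derive from :class:`ValueError`.
"""


class HsiColorError(Exception):
    """Base class for all hsicolor errors."""


class ValidationError(HsiColorError, ValueError):
    """Input violates a documented precondition (shape, range, schema)."""


class CalibrationError(HsiColorError, ValueError):
    """Calibration data are unusable, e.g. white minus dark is non-positive."""


class FormatError(HsiColorError, ValueError):
    """A file on disk does not conform to the expected format."""


class ConvergenceError(HsiColorError, RuntimeError):
    """An iterative solve failed to reach its target tolerance."""


class DetectionError(HsiColorError, RuntimeError):
    """Landmark detection failed (e.g. no face found)."""
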