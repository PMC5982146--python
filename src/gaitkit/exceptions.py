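"""Exception hierarchy for gaitkit.

All errors raised by the package derive from :class:`GaitKitError` so callers
can catch everything with one clause while still distinguishing parameter
misuse (a ``ValueError``) from runtime analysis failures.
"""


class GaitKitError(Exception):
    """Base class for all gaitkit errors."""


class ParameterError(GaitKitError, ValueError):
    """Invalid user-supplied parameter (non-positive rate, bad side, ...)."""


class FormatError(GaitKitError, ValueError):
    """Malformed input file: missing columns, non-uniform sampling, too short."""


class DetectionError(GaitKitError, RuntimeError):
    """Event detection cannot proceed (e.g. all-zero force trace)."""


class FeatureError(GaitKitError, RuntimeError):
    """A per-stride feature is undefined for the given window."""


class SummaryError(GaitKitError, RuntimeError):
    """Trial-level summarisation failed (e.g. no strides retained)."""


class ModelError(GaitKitError, RuntimeError):
    """Regression modelling failed (singular design, too few subjects)."""
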