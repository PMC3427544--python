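"""Exception hierarchy for athresh."""


class AthreshError(Exception):
    """Base class for all athresh errors."""


class ParameterError(AthreshError, ValueError):
    """Invalid distribution or procedure parameters."""


class DegenerateDataError(AthreshError, ValueError):
    """Input sample is degenerate (e.g. zero variance)."""


class FitFailureError(AthreshError, RuntimeError):
    """A mixture fit collapsed repeatedly or produced a pathological labeling."""


class InputError(AthreshError, ValueError):
    """Malformed or inconsistent input data (shapes, frame counts, masks, files)."""


class LayoutError(AthreshError, ValueError):
    """Simulated activation pattern does not fit the requested grid."""


class NumericError(AthreshError, RuntimeError):
    """Numerical procedure failed (unbracketed root, degenerate smoothness)."""
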