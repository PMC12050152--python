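"""Exception types shared across the package."""


class MFCError(Exception):
    """Base class for package errors."""


class ValidationError(MFCError, ValueError):
    """Input fails a structural or range check (formats, configs, matrices)."""


class DegenerateDistributionError(MFCError, ValueError):
    """A sample vector has no spread, so no density can be estimated."""


class AlignmentError(MFCError, ValueError):
    """Region or subject labels of two inputs do not match."""


class UndefinedCorrelationError(MFCError, ValueError):
    """A correlation is requested on a constant (zero-variance) input."""
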