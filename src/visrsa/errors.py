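"""Shared exception types."""


class VisRsaError(Exception):
    """Base class for all package errors."""


class ZeroVarianceError(VisRsaError):
    """A pattern or profile is constant where variance is required."""


class UndefinedCorrelationError(VisRsaError):
    """A correlation is undefined because one input has zero variance."""


class InvalidRdmError(VisRsaError):
    """A matrix violates the dissimilarity-matrix invariants."""
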