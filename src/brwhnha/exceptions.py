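"""Exception hierarchy for brwhnha."""


class BrwhnhaError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BrwhnhaError):
    """A file could not be parsed; the message carries line/cell coordinates."""


class ValidationError(BrwhnhaError, ValueError):
    """Inputs violate a documented precondition or invariant."""


class DegenerateBandwidthError(BrwhnhaError, ZeroDivisionError):
    """The Gaussian-kernel bandwidth is undefined because every interaction
    profile is zero (an all-zero association matrix)."""


class DegenerateRestartError(BrwhnhaError, ZeroDivisionError):
    """The restart matrix has zero total mass (no known associations at all),
    so it cannot be normalized to a probability matrix."""
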