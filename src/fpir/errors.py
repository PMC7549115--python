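"""Exception hierarchy for fpir."""


class FPIRError(Exception):
    """Base class for all fpir errors."""


class InputError(FPIRError, ValueError):
    """Malformed input: unknown columns, bad configuration, degenerate data."""


class DomainError(FPIRError, ValueError):
    """Data outside the domain a fractional power requires (e.g. negative base)."""


class SingularModelError(FPIRError, ValueError):
    """Design matrix is rank deficient; message names the collinear terms."""


class InsufficientDataError(FPIRError, ValueError):
    """Fewer rows than model parameters."""


class NoValidModelError(FPIRError, RuntimeError):
    """Every exponent candidate produced an invalid (non-finite or singular) model."""
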