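"""Exception hierarchy shared across the package."""


class MRPipeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MRPipeError):
    """A configuration problem: missing column, bad threshold, absent file."""


class ValidationError(MRPipeError):
    """A record violates a domain invariant."""


class RowError(ValidationError):
    """A malformed row in a delimited input file.

    Carries the 1-based line number of the offending row so the user can
    locate it in the source file.
    """

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class DuplicateVariantError(ValidationError):
    """The same snp_id appears more than once for one trait."""


class InsufficientInstrumentsError(MRPipeError):
    """An estimator was called with fewer instruments than it requires."""


class UndefinedRatioError(MRPipeError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class EstimationError(MRPipeError):
    """Numerical estimation failed (non-convergence, singular design)."""
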