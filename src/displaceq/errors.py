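"""Exception hierarchy shared by all displaceq modules."""


class DisplaceqError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DisplaceqError, ValueError):
    """Invalid input value or parameter (wrong sign, non-finite, out of range)."""


class ParseError(DisplaceqError, ValueError):
    """A string or file cell could not be parsed.

    ``position`` carries the 0-based offset (for strings) or line number
    (for files) of the offending token when known.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class SchemaError(DisplaceqError, ValueError):
    """A tabular input is missing required columns or has the wrong shape."""


class PlateValidationError(DisplaceqError, ValueError):
    """A plate is missing required control wells or has an invalid layout."""


class FitError(DisplaceqError, RuntimeError):
    """A nonlinear fit failed to converge or produced invalid estimates."""


class IdentifiabilityError(FitError):
    """The data cannot constrain the model (flat series, unbracketed transition)."""


class ConvergenceError(DisplaceqError, RuntimeError):
    """A numeric solver did not reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateWindowError(DisplaceqError, ValueError):
    """Positive and negative control means coincide: no assay window."""
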