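"""Exception hierarchy shared across the package."""


class DietRiskError(Exception):
    """Base class for all package errors."""


class ValidationError(DietRiskError, ValueError):
    """A numeric precondition was violated (negative dose, zero RfD, ...)."""


class SchemaError(DietRiskError, ValueError):
    """An input table does not conform to the documented CSV schema."""


class FitError(DietRiskError, RuntimeError):
    """A distribution fit is degenerate or infeasible."""
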