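"""Exception hierarchy for the cnsot package."""


class CnsotError(Exception):
    """Base class for all package errors."""


class DomainError(CnsotError, ValueError):
    """An input is outside the mathematical domain of an operation.

    The message names the offending field.
    """


class UnsupportedOperationError(CnsotError, TypeError):
    """The operation is not defined for the given object state.

    Raised, e.g., when a risk probability is requested from an
    interpolated-MET parameter set that carries no scale sigma.
    """


class IdentifiabilityError(CnsotError, ValueError):
    """The dataset cannot identify the model parameters.

    Raised for single-PO2 datasets (the exponent c is confounded with the
    location mu) and for all-censored datasets.
    """


class ConvergenceError(CnsotError, RuntimeError):
    """Numerical optimisation failed to converge."""
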