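"""Exception hierarchy for capdyn.

All capdyn-specific failures derive from :class:`CapdynError` so callers can
distinguish modelling failures (degenerate data, non-convergence) from
programming errors.
"""


class CapdynError(Exception):
    """Base class for all capdyn errors."""


class DomainError(CapdynError, ValueError):
    """An argument is outside its mathematical domain (e.g. probability > 1)."""


class InputError(CapdynError, ValueError):
    """Malformed input data (bad capture history, missing covariate, bad file)."""


class EmptyCategoryError(CapdynError):
    """A capture-history category has no observations, so the multinomial
    model is not estimable."""

    def __init__(self, category: int):
        self.category = int(category)
        super().__init__(
            f"capture-history category {category} has no observations; "
            "the multinomial model is not estimable"
        )


class ConvergenceError(CapdynError):
    """An iterative fit failed to converge.  Carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        self.trace = trace if trace is not None else []
        super().__init__(message)


class InsufficientDataError(CapdynError):
    """Too few observations for the requested model."""


class MissingValuesError(CapdynError):
    """A series contains missing values where none are allowed."""


class DegenerateDataError(CapdynError):
    """Data admit no meaningful fit (e.g. an all-zero count series)."""


class UnsupportedOperationError(CapdynError):
    """The requested operation is not defined for this fit mode."""
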