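"""Typed exceptions so callers can distinguish bad input from degenerate statistics."""


class ForestStabError(Exception):
    """Base class for all package-specific errors."""


class InputError(ForestStabError, ValueError):
    """Invalid user input: missing values, shapes, or out-of-range parameters."""


class SchemaError(ForestStabError, ValueError):
    """Predictor tables disagree in column names or order."""


class UndefinedStabilityError(ForestStabError, ArithmeticError):
    """An agreement statistic is undefined for the given ratings matrix.

    Raised when both between- and within-subject variance vanish (ICC) or
    the expected chance agreement is exactly 1 (Fleiss' kappa), i.e. when the
    matrix carries no information about run-to-run stability.
    """


class FittingError(ForestStabError, RuntimeError):
    """Nonlinear least squares failed to converge; carries diagnostics."""

    def __init__(self, message, *, init=None, residuals=None):
        super().__init__(message)
        self.init = init
        self.residuals = residuals
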