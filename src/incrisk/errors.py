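"""Exception hierarchy shared across the package."""


class IncriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IncriskError):
    """An invalid parameter or configuration value; the message names the field."""


class DataError(IncriskError):
    """A malformed or inconsistent cohort table / data dictionary."""


class CalibrationError(IncriskError):
    """Prevalence targets unreachable under the current generator shape.

    Carries ``achieved``: the best prevalences reached before giving up.
    """

    def __init__(self, message: str, achieved=None):
        super().__init__(message)
        self.achieved = achieved


class SeparationError(IncriskError):
    """Complete (or quasi-complete) separation detected in a logistic fit."""


class ConvergenceError(IncriskError):
    """IRLS failed to converge; carries the last iterate for inspection."""

    def __init__(self, message: str, last_coef=None, last_loglik=None, n_iter=None):
        super().__init__(message)
        self.last_coef = last_coef
        self.last_loglik = last_loglik
        self.n_iter = n_iter
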