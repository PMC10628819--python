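"""Exception hierarchy for astpredict."""


class AstPredictError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AstPredictError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(AstPredictError, ValueError):
    """A value outside the mathematical domain of an operation."""


class MissingCovariateError(AstPredictError, KeyError):
    """A model covariate required for prediction is absent."""


class RangeError(AstPredictError, ValueError):
    """A target value is unattainable within the search window."""


class ImputationError(AstPredictError, ValueError):
    """Imputation cannot proceed (e.g. a variable is entirely missing)."""


class SelectionError(AstPredictError, ValueError):
    """Fractional-polynomial power selection cannot proceed."""


class SingularFitError(AstPredictError, ValueError):
    """The design matrix is rank deficient."""


class DevelopmentError(AstPredictError, RuntimeError):
    """Too many bootstrap replicates failed during model development."""


class CalibrationError(AstPredictError, ValueError):
    """Calibration statistics are undefined for the given inputs."""


class DiscriminationError(AstPredictError, ValueError):
    """ROC discrimination is undefined (single outcome class)."""


class CiError(AstPredictError, RuntimeError):
    """A bootstrap confidence interval could not be computed."""


class GroupingError(AstPredictError, ValueError):
    """A grouped cross-validation request is invalid."""


class PolicyError(AstPredictError, ValueError):
    """A benefit-policy threshold target is unattainable."""
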