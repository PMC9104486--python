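"""Exception hierarchy shared across the package."""


class RadonArmaxError(Exception):
    """Base class for all errors raised by radon-armax."""


class FormatError(RadonArmaxError):
    """A CSV log could not be parsed (bad timestamp, missing column...)."""


class EmptyInputError(RadonArmaxError):
    """An input file or series contained no data rows."""


class AlignmentError(RadonArmaxError):
    """Radon and weather logs do not overlap in time."""


class ParameterError(RadonArmaxError, ValueError):
    """An argument violates its contract (even window, bad cutoff...)."""


class InsufficientDataError(RadonArmaxError):
    """Not enough valid history to build regressors or fit a model."""


class DegeneracyError(RadonArmaxError):
    """The regression problem is rank deficient."""


class SearchFailureError(RadonArmaxError):
    """Every cell of an order grid failed to fit."""


class ScenarioError(RadonArmaxError):
    """A synthetic scenario configuration is infeasible."""


class CoverageError(RadonArmaxError):
    """Exogenous series do not cover the requested simulation horizon."""


class UndefinedMetricError(RadonArmaxError):
    """A validation metric is undefined (zero mean, constant series...)."""


class UnstableModelWarning(UserWarning):
    """A fitted or supplied A(q) polynomial has roots on/outside the unit circle."""
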