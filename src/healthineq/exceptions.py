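"""Exception types raised by healthineq estimators and statistics."""


class HealthineqError(ValueError):
    """Base class for all package-specific errors."""


class UndefinedIndexError(HealthineqError):
    """Concentration index undefined (e.g. outcome mean is zero)."""


class DegenerateOutcomeError(HealthineqError):
    """Binary outcome has no variation (all zeros or all ones)."""


class SeparationError(HealthineqError):
    """Probit likelihood unbounded: a covariate perfectly predicts the outcome."""


class NonIdentifiableScaleError(HealthineqError):
    """Interval-censored scale parameter not identified (single band observed)."""


class InsufficientDataError(HealthineqError):
    """Too few observations for the requested statistic."""
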