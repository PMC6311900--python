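"""Exception hierarchy for mr2sample."""


class MRError(Exception):
    """Base class for all mr2sample errors."""


class ConfigurationError(MRError):
    """Bad user configuration (missing column, unknown option value, ...)."""


class ValidationError(MRError):
    """Input data violates a documented invariant."""


class UndefinedRatioError(MRError):
    """Wald ratio requested for a variant with zero exposure effect."""


class InsufficientInstrumentsError(MRError):
    """An estimator was given fewer variants than it needs."""


class DegenerateInstrumentsError(MRError):
    """All exposure effects are zero (or collinear) - no identification."""


class NonConvergenceError(MRError):
    """Iterative optimisation failed to converge within the iteration cap.

    Carries the last iterate in ``last_estimate``.
    """

    def __init__(self, message: str, last_estimate: float | None = None):
        super().__init__(message)
        self.last_estimate = last_estimate


class EmptySelectionError(MRError):
    """A selection / screening step removed every candidate."""
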