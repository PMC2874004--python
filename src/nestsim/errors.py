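"""Exception hierarchy for nestsim."""


class NestSimError(Exception):
    """Base class for all nestsim errors."""


class ConfigurationError(NestSimError):
    """An invalid simulation configuration; the message names the field."""


class ParameterError(NestSimError):
    """An invalid estimator or experiment parameter."""


class BoundsError(NestSimError):
    """A coordinate outside the simulation grid."""


class PlacementError(NestSimError):
    """Transects could not be placed without overlap."""


class InsufficientDataError(NestSimError):
    """An observation table with too few surveys or transitions."""


class UndefinedDecayError(NestSimError):
    """The fitted stage-transition chain has no route to disappearance.

    Carries a machine-readable ``reason`` (e.g. ``"no-complete-decay"``) so
    callers can record why an estimate is undefined rather than silently
    dropping the replicate.
    """

    def __init__(self, reason: str = "no-complete-decay", message: str | None = None):
        self.reason = reason
        super().__init__(message or f"nest decay time undefined: {reason}")


class FixtureError(NestSimError):
    """An inconsistent fixture specification."""


class SummaryError(NestSimError):
    """A summary was requested over records that contain no defined estimate."""
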