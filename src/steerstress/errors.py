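"""Exception hierarchy for the steering-stress pipeline.

Each stage raises a narrow subclass so callers (and the segment pipeline,
which converts failures into drop reasons) can react per failure mode.
"""


class SteerStressError(Exception):
    """Base class for all package errors."""


class FormatError(SteerStressError):
    """A CSV/table does not match the expected dialect (e.g. missing columns)."""


class AngleRangeError(SteerStressError):
    """A steering-angle sample exceeds the physical +/-450 degree range."""


class EmptyTraceError(SteerStressError):
    """An operation requiring samples received an empty trace."""


class InsufficientDataError(SteerStressError):
    """Too few samples/values for the requested computation."""


class DegenerateSegmentError(SteerStressError):
    """A constant segment cannot be min-max scaled."""


class ConditioningError(SteerStressError):
    """The autocorrelation normal equations are numerically singular."""


class NoOscillatoryModeError(SteerStressError):
    """All prediction-polynomial roots are real: no damped frequency exists."""


class MissingGroupError(SteerStressError):
    """A condition-by-scope group required for the fitting threshold is absent."""


class SweepEmptyError(SteerStressError):
    """No turn segments were found at any upper-bound sweep point."""


class ScheduleError(SteerStressError):
    """Simulated turn events overlap in time."""


class UndefinedEffectError(SteerStressError):
    """Effect size undefined (zero pooled standard deviation)."""


class SegmentDropped(SteerStressError):
    """A segment was excluded from analysis; carries a machine-readable reason."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)
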