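"""Exception hierarchy for the sprint velocity pipeline.

Every stage raises a subclass of :class:`SprintFusionError`, so callers can
catch pipeline failures without swallowing unrelated bugs.
"""


class SprintFusionError(Exception):
    """Base class for all errors raised by sprintfusion."""


class FormatError(SprintFusionError):
    """A file does not conform to the expected CSV/config layout."""


class DataError(SprintFusionError):
    """The file parsed, but the data violates an invariant (e.g. time not
    strictly increasing, negative ground speed)."""


class ConfigError(SprintFusionError):
    """A session configuration value is invalid."""


class ParameterError(SprintFusionError, ValueError):
    """A model or simulator parameter violates its sign/ordering constraints."""


class EmptySeriesError(SprintFusionError):
    """An operation received an empty time series."""


class NoStaticPeriodError(SprintFusionError):
    """The accelerometer data before the start is not consistent with the
    sensor being at rest (mean specific force far from gravity)."""


class NoSprintFoundError(SprintFusionError):
    """The GNSS speed never exceeds the start threshold."""


class SprintIncompleteError(SprintFusionError):
    """The integrated distance never reaches the configured sprint distance."""


class FitError(SprintFusionError):
    """A model fit could not be computed (bad anchor, optimizer failure)."""
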