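"""Exception hierarchy for the tubepump pipeline.

Every stage raises a subclass of :class:`TubepumpError` so callers can
distinguish pipeline failures from programming errors.
"""


class TubepumpError(Exception):
    """Base class for all tubepump errors."""


class InvalidConfigurationError(TubepumpError, ValueError):
    """A configuration value is out of its admissible range."""


class OcclusionInconsistencyError(TubepumpError):
    """Nonzero flux is required through a fully closed lumen."""


class AperiodicityError(TubepumpError):
    """No heartbeat period could be detected in a frame sequence."""


class SynchronizationError(TubepumpError):
    """Cross-slice phase synchronization failed (e.g. inconsistent periods)."""


class OutOfBoundsError(TubepumpError, ValueError):
    """A measurement plane or phase index lies outside the volume."""


class AmbiguousSegmentationError(TubepumpError):
    """Several lumen candidates of similar size; a region of interest is needed."""


class InsufficientDataError(TubepumpError):
    """Too few contiguous samples for the requested statistical test."""


class DegenerateInputError(TubepumpError, ValueError):
    """A statistical input has zero variance or is otherwise degenerate."""


class RankDeficiencyError(TubepumpError):
    """Lagged regressors are perfectly collinear."""


class UndefinedAngleError(TubepumpError, ValueError):
    """Doppler angle at or beyond 90 degrees: axial projection undefined."""
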