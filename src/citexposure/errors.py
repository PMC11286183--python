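"""Exception hierarchy for citexposure.

All package errors derive from :class:`CitexposureError` so callers can
catch everything in one clause; most also derive from ``ValueError`` so
loose validation code keeps working.
"""


class CitexposureError(Exception):
    """Base class for all citexposure errors."""


class ParameterError(CitexposureError, ValueError):
    """A model or run parameter is outside its admissible range."""


class InvalidEcologyError(ParameterError):
    """The reference class is empty (R < 1) or otherwise ill-formed."""


class InvalidUnitsError(ParameterError):
    """Initial exposure units are nonpositive or of the wrong length."""


class InvalidArticleError(CitexposureError, IndexError):
    """An article index lies outside [0, R)."""


class ShapeError(CitexposureError, ValueError):
    """Vector or matrix operands have incompatible shapes."""


class InsufficientDataError(CitexposureError, ValueError):
    """A statistic was requested on an empty or too-small sample."""


class DegenerateSampleError(InsufficientDataError):
    """A sample has zero spread where spread is required (KDE, skewness)."""


class InsufficientRunsError(InsufficientDataError):
    """Fewer than two runs were supplied for a pairwise upper bound."""


class InvalidBoundError(CitexposureError, ValueError):
    """An overlap upper bound is nonpositive."""


class EmptyChoiceError(CitexposureError, RuntimeError):
    """No memory trace has positive activation under the current probe."""


class MissingTrajectoryError(CitexposureError, ValueError):
    """A trajectory operation was requested on a run without tracking."""


class CountsFormatError(CitexposureError, ValueError):
    """A citation-counts table violates the TSV contract."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
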