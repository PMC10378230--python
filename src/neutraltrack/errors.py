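"""Exception hierarchy shared across the package.

Geometry errors signal degenerate or impossible constructions; landmark
errors signal bad input files; stats errors signal invalid samples.
"""


class NeutralTrackError(Exception):
    """Base class for all package errors."""


class GeometryError(NeutralTrackError, ValueError):
    """Base class for geometric construction failures."""


class DegenerateGeometryError(GeometryError):
    """Inputs are collinear/coincident/parallel where they must not be."""


class NoIntersectionError(GeometryError):
    """A requested intersection does not exist."""


class BranchAmbiguityError(GeometryError):
    """A branch selector failed to isolate a single candidate point."""


class LandmarkError(NeutralTrackError, ValueError):
    """Base class for landmark input problems."""


class MissingLandmarkError(LandmarkError):
    """Required landmark names absent from an input file."""

    def __init__(self, names):
        self.names = tuple(names)
        super().__init__(f"missing required landmark(s): {', '.join(self.names)}")


class DuplicateLandmarkError(LandmarkError):
    """The same landmark appears more than once in an input file."""


class MalformedFileError(LandmarkError):
    """Unparseable landmark file; carries the 1-based offending line number."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ReportValidationError(NeutralTrackError, ValueError):
    """An analysis report failed validation (e.g. non-finite angle)."""


class StatsError(NeutralTrackError, ValueError):
    """Base class for statistical procedure errors."""


class InsufficientDataError(StatsError):
    """Too few observations for the requested statistic."""


class ZeroVarianceError(StatsError):
    """A sample (or difference sample) has zero variance."""


class LengthMismatchError(StatsError):
    """Paired samples have unequal lengths."""


class UnknownLandmarkWarning(UserWarning):
    """An input file contains a landmark name the parser does not know."""
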