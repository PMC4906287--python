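"""Exception hierarchy shared by all modules."""


class IsrError(Exception):
    """Base class for all package errors."""


class FormatError(IsrError):
    """Input file does not have the expected structure (missing columns, empty file)."""


class ParseError(IsrError):
    """A field could not be parsed; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(IsrError):
    """Records violate a panel-level invariant (duplicate ids, ambiguous wild type)."""


class InsufficientDataError(IsrError):
    """Too few observations for the requested statistic."""


class DegenerateLandscapeError(IsrError):
    """All decoys share one energy: roughness is zero and the ISR is undefined."""


class UnstableEstimateError(IsrError):
    """Bootstrap discarded too many degenerate resamples to report an interval."""


class UsageError(IsrError):
    """Caller passed inconsistent arguments (unknown format/field, length mismatch)."""
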