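"""Exception hierarchy for the phantomech pipeline."""


class PhantomechError(Exception):
    """Base class for all pipeline errors."""


class CurveParseError(PhantomechError):
    """A data file row could not be parsed.

    Parameters
    ----------
    message : str
        Human-readable description.
    line_number : int, optional
        1-based line number of the offending row.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class InsufficientDataError(PhantomechError):
    """Fewer usable data points than the operation requires."""


class UnloadSegmentError(PhantomechError):
    """Strain decreases within a record (unload segment present)."""


class ReplicateLoadError(PhantomechError):
    """No replicate files matched, or one or more files failed validation."""


class ConvergenceError(PhantomechError):
    """An iterative fit failed to converge after all restarts."""

    def __init__(self, message: str, last_state=None):
        self.last_state = last_state
        super().__init__(message)


class SingularParameterError(PhantomechError):
    """A parameter value makes the model undefined (e.g. alpha = -1)."""
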