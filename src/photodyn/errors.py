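"""Exception hierarchy.

Every error raised by the package derives from :class:`PhotodynError` so
callers (and the CLI) can map error classes onto exit codes.
"""


class PhotodynError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidInputError(PhotodynError):
    """Malformed or inconsistent user input (shapes, values, formats)."""

    exit_code = 3


class ParseError(InvalidInputError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConvergenceError(PhotodynError):
    """An iterative procedure (training, optimization, fit) failed to converge."""

    exit_code = 4


class TrainingDivergedError(ConvergenceError):
    """Non-finite loss encountered during network training."""


class PhaseTrackingError(PhotodynError):
    """Wavefunction phases could not be decided along an interpolation path."""

    exit_code = 5

    def __init__(self, message: str, undecided_states: tuple[int, ...] = ()):
        self.undecided_states = tuple(undecided_states)
        super().__init__(message)


class TrajectoryAbortError(PhotodynError):
    """Dynamics propagation hit a non-finite force or energy."""

    exit_code = 6
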