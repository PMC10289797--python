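"""Named exceptions raised by the pipeline stages."""


class PaniclephenoError(Exception):
    """Base class for all package-specific errors."""


class UnknownModeError(PaniclephenoError, ValueError):
    """Sampling-schedule mode is not one of the supported protocols."""


class SceneLayoutError(PaniclephenoError, ValueError):
    """The requested panicle population does not fit the plot grid."""


class EmptyScheduleError(PaniclephenoError, ValueError):
    """A sampling schedule with no days/timestamps was supplied."""


class InvalidBoxError(PaniclephenoError, ValueError):
    """A bounding box has non-positive width or height."""


class MissingDayError(PaniclephenoError, KeyError):
    """The requested day is not present in the detection stream."""


class DeletedTrackError(PaniclephenoError, ValueError):
    """An operation was requested on a track that has been deleted."""


class EmptyFrameError(PaniclephenoError, ValueError):
    """Tracking accuracy is undefined when the first frame holds no panicles."""


class NoPlateauError(PaniclephenoError, ValueError):
    """Daily panicle counts never rise above zero; no plateau exists."""


class NoFloweringError(PaniclephenoError, ValueError):
    """No day reaches the minimum flowering panicle count."""


class TrackJoinError(PaniclephenoError, ValueError):
    """A cross-day identity map assigns two same-day tracks to one panicle."""


class KeyMismatchError(PaniclephenoError, KeyError):
    """Two paired mappings do not share the same keys."""


class DegenerateInputError(PaniclephenoError, ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""


class StreamParseError(PaniclephenoError, ValueError):
    """A detection-stream or ground-truth file failed validation."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
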