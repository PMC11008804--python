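"""Exception hierarchy for the segmentation pipeline.

Every stage raises a subclass of :class:`RepsegError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class RepsegError(Exception):
    """Base class for all pipeline errors."""


class AudioFormatError(RepsegError):
    """File is not a readable WAV container or has an unusable layout."""


class SilentSignalError(RepsegError):
    """An operation that needs non-zero amplitude received digital silence."""


class AnnotationError(RepsegError):
    """A parse annotation violates ordering / overlap invariants."""


class CountOutOfRangeError(RepsegError):
    """A repetition count falls outside the reference bank's range."""


class PathologicalWarpError(RepsegError):
    """Boundary transfer produced a degenerate (zero-length) interval."""
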