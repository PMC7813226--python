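"""Exception hierarchy for voxseg.

Every error raised by the library derives from :class:`VoxsegError`, so
callers (and the CLI) can distinguish data errors from programming errors.
"""


class VoxsegError(Exception):
    """Base class for all voxseg data errors."""


class DimensionMismatchError(VoxsegError):
    """Grids that must share a shape do not."""


class UnsupportedFormatError(VoxsegError):
    """Sample format outside the supported unsigned 8/16-bit grayscale set."""


class EmptyInputError(VoxsegError):
    """An operation received no data (e.g. an empty slice list)."""


class CorruptVolumeError(VoxsegError):
    """Raw payload size disagrees with its sidecar header."""


class InvalidArgumentError(VoxsegError):
    """A parameter value violates an operation's precondition."""


class SeedNotInSelectionError(VoxsegError):
    """Region-grow seed lies outside the selection mask."""


class MissingSeedsError(VoxsegError):
    """Graph cut requires at least one foreground and one background seed."""


class EmptySelectionError(VoxsegError):
    """A mask or tag selection that must be non-empty is empty."""


class EmptyContourError(VoxsegError):
    """Contour interpolation requires both endpoint masks to be non-empty."""
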