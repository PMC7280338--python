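"""Exception hierarchy for weargaze.

Recoverable per-line packet problems raise :class:`PacketError`; everything
that invalidates a whole recording or operation raises a more specific
subclass of :class:`WearGazeError`.
"""


class WearGazeError(Exception):
    """Base class for all weargaze errors."""


class PacketError(WearGazeError):
    """A single packet line could not be decoded (recoverable: skip + count)."""


class UnknownPacketKind(PacketError):
    """A syntactically valid packet of a kind this dialect does not model."""


class ParseError(WearGazeError):
    """A recording or segment could not be parsed (fatal for that recording)."""


class SegmentOverlapError(ParseError):
    """Two segments of one recording overlap in time."""


class ConfigError(WearGazeError):
    """Invalid configuration or parameter value."""


class RecordingNotFoundError(WearGazeError):
    """Lookup miss: no recording matches the query."""


class AmbiguousRecordingError(WearGazeError):
    """Lookup query matches more than one recording."""


class AnnotationError(WearGazeError):
    """Base class for event-stream editing errors."""


class OverlapError(AnnotationError):
    """An edit would create overlapping annotations."""


class RangeError(AnnotationError):
    """A time argument falls outside its allowed range."""


class FlagError(AnnotationError):
    """A flag is not valid for the annotation's label."""


class CategoryError(AnnotationError):
    """A label is not among the stream's configured categories."""


class LockedStreamError(AnnotationError):
    """Attempt to edit a locked (automatically generated) stream."""


class NoOpError(AnnotationError):
    """The requested edit would have no effect (e.g. split on a boundary)."""


class EventFileFormatError(AnnotationError):
    """A text event file violates the expected format."""


class StreamValidationError(AnnotationError):
    """A classifier or file produced a stream violating stream invariants."""
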