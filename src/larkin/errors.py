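"""Exception hierarchy.

All data-level failures derive from :class:`DataError` so the CLI can map
them to a single exit code distinct from usage errors.
"""


class DataError(Exception):
    """Base class for invalid or inconsistent input data."""


class InvalidAnnotationError(DataError):
    """A structure annotation violates its invariants (bad polygon, empty mask...)."""


class AnnotationParseError(DataError):
    """An annotation file could not be parsed; message names frame and field."""


class CalibrationError(DataError):
    """Non-positive or missing calibration reference."""


class EventError(DataError):
    """Swallow-event selection or measurement impossible on this trajectory."""


class PhantomError(DataError):
    """Phantom specification is invalid (e.g. structure leaves the frame)."""
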