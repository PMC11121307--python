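"""Exception hierarchy.

Validation errors (bad user input, malformed configs) are distinguished from
structural/parse errors on files and from numerical degeneracies so that the
CLI can map them onto distinct exit codes.
"""


class HalfChannelError(Exception):
    """Base class for all package errors."""


class ValidationError(HalfChannelError):
    """Invalid argument values, inconsistent schemas, bad configuration."""


class ParseError(HalfChannelError):
    """A file could not be parsed; message names the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StructureError(HalfChannelError):
    """Structurally inconsistent input (atom-count mismatch, missing atoms)."""


class SelectionError(HalfChannelError):
    """An atom selection expression did not resolve."""


class DegenerateGeometryError(HalfChannelError):
    """Coordinates too degenerate for the requested operation (collinear etc.)."""


class InsufficientFramesError(HalfChannelError):
    """Operation needs more trajectory frames than were provided."""
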