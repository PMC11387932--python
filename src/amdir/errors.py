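"""Exception hierarchy.

Exceptions signal *usage* problems (malformed inputs, bad arguments,
unreachable resources).  Problems *in the data being curated* are never
raised: they are collected into a :class:`~amdir.validation.ValidationReport`
so a curator sees every issue at once.
"""


class AmdirError(Exception):
    """Base class for all toolkit errors."""


class TableParseError(AmdirError):
    """Structurally broken TSV input (ragged row, undecodable bytes)."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class SerializationError(AmdirError):
    """A cell cannot be represented in the TSV dialect (embedded tab/newline)."""


class SchemaConsistencyError(AmdirError):
    """A schema document violates its own invariants (dangling enum_ref, no columns)."""


class SchemaBindingError(AmdirError):
    """A table's header does not match the schema it is being bound to."""


class ReleaseNotFoundError(AmdirError):
    """The requested release tag has no published table."""


class TransportError(AmdirError):
    """A network or fixture-store fetch failed; distinct from parse errors."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


class ConversionError(AmdirError):
    """A table cannot be converted (inconsistent file lists, unknown instrument)."""


class MergeError(AmdirError):
    """Tables cannot be merged (header mismatch or duplicate keys)."""


class CapacityError(AmdirError):
    """A fixture bundle is too small to host the requested corruptions."""


class UsageError(AmdirError):
    """An operation was invoked with arguments that cannot be honoured."""
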