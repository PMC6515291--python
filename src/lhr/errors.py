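"""Exception hierarchy for the LHR integration pipeline."""

from __future__ import annotations


class LHRError(Exception):
    """Base class for every error raised by this package."""


class MalformedDocumentError(LHRError):
    """A source document could not be parsed in its declared format.

    Carries the underlying parser message, which names the offending
    line/position where the parser reports one.
    """

    def __init__(self, message: str, *, source: str | None = None):
        self.source = source
        super().__init__(message if source is None else f"{source}: {message}")


class InvalidExtensionError(LHRError):
    """A mapping extension contains axioms outside the permitted profile.

    ``offending`` lists the triples (as 3-tuples) that violate the profile.
    """

    def __init__(self, message: str, offending=()):
        self.offending = list(offending)
        super().__init__(message)


class UnsupportedFormatError(LHRError):
    """An RDF serialization format outside the supported set was requested."""


class QueryParseError(LHRError):
    """A SPARQL query failed to parse; message includes the parser position."""


class ManifestError(LHRError):
    """A source manifest violates its schema; message names the field path."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(message if field is None else f"{field}: {message}")
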