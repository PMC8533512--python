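"""Exception hierarchy shared across the package."""


class GeoHarvestError(Exception):
    """Base class for all package errors."""


class ValidationError(GeoHarvestError):
    """Input or record violates a schema invariant."""


class ParseError(GeoHarvestError):
    """A document is not well-formed XML; carries the source position."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (at line {line}, column {column})"
        super().__init__(message)


class FormatError(GeoHarvestError):
    """Well-formed XML that lacks the expected structure for an endpoint."""


class FetchError(GeoHarvestError):
    """A fetch failed; ``transient`` marks retry-exhaustion vs hard failures."""

    def __init__(self, message: str, endpoint: str, status: int | None = None,
                 transient: bool = False):
        self.endpoint = endpoint
        self.status = status
        self.transient = transient
        super().__init__(f"{message} [endpoint={endpoint}, status={status}]")


class ResolutionError(GeoHarvestError):
    """A literature identifier could not be resolved; carries the raw ID."""

    def __init__(self, raw_id: str):
        self.raw_id = raw_id
        super().__init__(f"could not resolve reference identifier {raw_id!r}")
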