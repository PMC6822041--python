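"""Exception hierarchy shared across the package."""


class ClawMorphError(Exception):
    """Base class for all package-specific errors."""


class MalformedRecordError(ClawMorphError):
    """A TPS record violates the landmark/curve layout contract."""


class TPSParseError(ClawMorphError):
    """A TPS file could not be tokenised; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TreeError(ClawMorphError):
    """Invalid phylogeny input (duplicate tips, missing branch lengths, ...)."""


class DegenerateGeometryError(ClawMorphError):
    """Three points defining a circle are collinear within tolerance."""


class ValidationError(ClawMorphError):
    """A domain-type invariant was violated."""
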