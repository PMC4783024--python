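"""Exception hierarchy.

User-facing errors (bad input data, unresolvable identifiers, malformed
views) derive from :class:`AnatogramError`; the CLI maps these to exit
status 2 and anything else to exit status 1.
"""


class AnatogramError(Exception):
    """Base class for user-correctable errors."""


class DataFormatError(AnatogramError):
    """A delimited table or lookup file violates the expected format."""


class GeneNotFoundError(AnatogramError):
    """No lookup record or measurement row matches the query."""

    def __init__(self, query: str, message: str | None = None):
        self.query = query
        super().__init__(message or f"gene not found: {query!r}")


class AmbiguousGeneError(AnatogramError):
    """A symbol query matched more than one lookup record."""

    def __init__(self, query: str, candidates: list[str]):
        self.query = query
        self.candidates = list(candidates)
        super().__init__(
            f"symbol {query!r} is ambiguous; candidates: {', '.join(candidates)}"
        )


class ViewError(AnatogramError):
    """A view definition or its XML serialization is invalid."""


class NormalizationError(AnatogramError):
    """Array scaling cannot proceed (e.g. non-positive trimmed mean)."""


class StageError(AnatogramError):
    """Wraps an error with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
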