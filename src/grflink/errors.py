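"""Exception hierarchy shared across the package."""


class GrfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GrfError, ValueError):
    """An input object violates a documented invariant."""


class KBFormatError(GrfError, ValueError):
    """A knowledge-base file does not conform to the canonical dialect.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(GrfError, ValueError):
    """Components are wired together inconsistently (e.g. dim mismatch)."""


class ProviderError(GrfError, RuntimeError):
    """A text-generation backend failed after retries. Retryable; distinct
    from validation errors so callers can decide to back off."""

    def __init__(self, message: str, mention_id: str | None = None):
        self.mention_id = mention_id
        if mention_id is not None:
            message = f"{message} (mention_id={mention_id})"
        super().__init__(message)
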