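"""Exception hierarchy shared across the pipeline stages."""


class AtopiaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AtopiaError):
    """A configuration value is missing, out of range, or inconsistent."""


class MissingInputError(AtopiaError):
    """A required input file is absent."""


class ParseError(AtopiaError):
    """A delimited input file contains a malformed value."""


class IntegrityError(AtopiaError):
    """A foreign key does not resolve or table invariants are violated."""


class InvalidInputError(AtopiaError):
    """An operation received arguments outside its contract."""


class DateOrderError(InvalidInputError):
    """A date interval is reversed (end precedes start)."""


class EmptyCohortError(AtopiaError):
    """An operation that needs a non-empty cohort received none."""


class PipelineStageError(AtopiaError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
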