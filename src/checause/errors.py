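"""Exception hierarchy shared across the pipeline."""


class CheCauseError(Exception):
    """Base class for all package errors."""


class ConfigError(CheCauseError):
    """A configuration value is invalid; the message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field '{field}': {message}")


class SchemaError(CheCauseError):
    """An input table violates the published schema."""


class IntegrityError(CheCauseError):
    """Referential integrity between tables is broken."""


class CodebookError(CheCauseError):
    """A raw reason code is absent from the codebook."""


class PipelineOrderError(CheCauseError):
    """A stage was invoked before its inputs were produced."""
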