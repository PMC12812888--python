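"""Exception hierarchy shared across the pipeline stages."""


class AgrigraphError(Exception):
    """Base class for all package errors."""


class ConfigError(AgrigraphError):
    """Invalid or inconsistent configuration."""


class SchemaError(AgrigraphError):
    """Input data does not match the required schema."""


class DataError(AgrigraphError):
    """A data-stage precondition was violated (empty input, bad id, ...)."""


class IntegrityError(AgrigraphError):
    """A cross-reference inside an index bundle does not resolve."""

    def __init__(self, message: str, dangling_id: str | None = None):
        super().__init__(message)
        self.dangling_id = dangling_id


class ProviderError(AgrigraphError):
    """A model provider failed; retryable, distinct from malformed prompts."""


class MalformedPromptError(AgrigraphError):
    """The request handed to a provider was itself invalid."""


class TruncatedOutputError(AgrigraphError):
    """Provider output ended before the completion delimiter."""


class UndefinedMetricError(AgrigraphError):
    """A metric denominator is zero; the value is undefined, not 0."""
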