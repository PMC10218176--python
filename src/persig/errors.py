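"""Exception hierarchy shared across the pipeline stages."""


class PersigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PersigError):
    """A simulation or run configuration value is invalid."""


class InputError(PersigError):
    """Inputs violate a precondition (missing samples, empty universe, ...)."""


class DegenerateInputError(PersigError):
    """Inputs are formally valid but the statistic is undefined on them
    (zero global SD, a gene set equal to the whole universe, < 2 nodes)."""


class ParseError(PersigError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class PipelineError(PersigError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
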