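"""Exception hierarchy shared across the pipeline stages."""


class RefselError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(RefselError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(RefselError, ValueError):
    """A malformed input file (ragged rows, duplicate identifiers, bad tokens)."""


class ConsistencyError(RefselError, ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


class DegenerateDataError(RefselError, ValueError):
    """Data that cannot support the requested computation (e.g. one class only)."""


class StageError(RefselError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
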