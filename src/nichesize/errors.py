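"""Exception hierarchy shared across the package."""


class NicheSizeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NicheSizeError):
    """Invalid configuration: missing columns, bad parameter values."""


class FormatError(NicheSizeError):
    """Malformed or inconsistent input data."""


class DegenerateLimitsError(NicheSizeError):
    """Niche limits with n_max <= n_min: the position index is undefined."""


class StageError(NicheSizeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
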