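"""Exception hierarchy shared across the package."""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsmrError):
    """Invalid configuration: missing columns, bad thresholds, absent seeds."""


class ValidationError(TsmrError, ValueError):
    """A record, matrix or parameter violates a documented invariant."""


class NoSharedInstrumentsError(TsmrError):
    """Exposure and outcome summary sets share no SNP identifiers."""


class PipelineError(TsmrError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
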