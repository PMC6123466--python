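"""Exception hierarchy shared across the pipeline."""


class TumorOnlyError(Exception):
    """Base class for all package errors."""


class ConfigError(TumorOnlyError):
    """Invalid or unknown configuration value."""


class FormatError(TumorOnlyError):
    """A file does not conform to the expected dialect."""


class ValidationError(TumorOnlyError):
    """A record violates a domain invariant."""


class DegenerateInputError(TumorOnlyError):
    """Input is structurally valid but statistically degenerate."""


class ConvergenceError(TumorOnlyError):
    """Iterative fit failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PipelineError(TumorOnlyError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
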