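"""Exception types shared across the package."""


class SSFIRError(Exception):
    """Base class for package errors."""


class ParameterError(SSFIRError, ValueError):
    """Invalid model or generator parameters."""


class GenerationError(SSFIRError, RuntimeError):
    """Random-graph construction failed within the retry budget."""

    def __init__(self, message: str, attempts: int | None = None):
        super().__init__(message)
        self.attempts = attempts


class FormatError(SSFIRError, ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class BracketingError(SSFIRError, ValueError):
    """Root bracket does not straddle a sign change."""

    def __init__(self, message: str, f_lo: float, f_hi: float):
        super().__init__(message)
        self.f_lo = f_lo
        self.f_hi = f_hi


class ConfigError(SSFIRError, ValueError):
    """Invalid experiment configuration; lists offending keys."""

    def __init__(self, message: str, keys: list[str] | None = None):
        super().__init__(message)
        self.keys = keys or []
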