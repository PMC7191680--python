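"""Exception hierarchy shared across the package."""


class ClinstsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ClinstsError, ValueError):
    """An argument violates an operation's precondition."""


class StateError(ClinstsError, RuntimeError):
    """An object is used before it was fitted / loaded / initialized."""


class ConfigError(ClinstsError, ValueError):
    """A configuration object is internally inconsistent."""


class ParseError(ClinstsError, ValueError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TrainingError(ClinstsError, RuntimeError):
    """Model training diverged or produced non-finite losses."""


class UndefinedCorrelationError(ClinstsError, ValueError):
    """Pearson correlation requested for a constant input vector."""
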