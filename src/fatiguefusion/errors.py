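"""Exception hierarchy shared by all pipeline stages."""


class FatigueFusionError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FatigueFusionError, ValueError):
    """A parameter violates a documented precondition."""


class DetectionError(FatigueFusionError):
    """The eye-pair detector found no candidate region in a frame."""


class ValidationError(FatigueFusionError, ValueError):
    """Input data (log, manifest, feature table) fails schema validation."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NotFittedError(FatigueFusionError, RuntimeError):
    """A scorer or model was used before being fitted."""
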