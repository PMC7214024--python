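"""Exception hierarchy shared across the package."""


class FusionPriorError(Exception):
    """Base class for all package errors."""


class GenomeError(FusionPriorError):
    """Malformed or inconsistent genome FASTA."""


class AnnotationError(FusionPriorError):
    """Malformed or inconsistent gene annotation."""


class ParseError(FusionPriorError):
    """Tabular input that cannot be parsed; carries the offending row/line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ModelError(FusionPriorError):
    """Invalid model configuration or archive."""
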