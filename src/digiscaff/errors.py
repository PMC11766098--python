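"""Exception hierarchy shared across the toolkit."""


class DigiscaffError(Exception):
    """Base class for all digiscaff errors."""


class InputDataError(DigiscaffError, ValueError):
    """Input records are malformed or mutually inconsistent."""


class ParameterError(DigiscaffError, ValueError):
    """A caller-supplied parameter is out of its valid range."""


class ParseError(DigiscaffError, ValueError):
    """A delimited or sequence file could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class MissingToolError(DigiscaffError, RuntimeError):
    """A required external executable is not on PATH."""
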