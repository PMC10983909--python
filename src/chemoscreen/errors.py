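"""Exception hierarchy.

Validation failures (bad inputs, malformed files) and numerical failures
(non-convergence, degenerate fits) are distinguished so the CLI can map
them to distinct exit codes.
"""


class ChemoscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(ChemoscreenError, ValueError):
    """Malformed or inconsistent input; never silently coerced."""


class BedFormatError(ValidationError):
    """A BED line that cannot be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class NumericalError(ChemoscreenError, RuntimeError):
    """A numerical procedure failed to converge or is unidentifiable."""
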