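"""Exception types used across the package."""


class HistphenoError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(HistphenoError):
    """A file does not conform to the expected tab-delimited layout."""


class RowParseError(HistphenoError):
    """A single data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DegenerateDesignError(HistphenoError):
    """The data cannot identify the requested model (e.g. a single year with
    random year effects, or an error stratum with fewer than two records)."""


class UsageError(HistphenoError):
    """An operation was invoked on an object of the wrong kind."""
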