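"""Exception hierarchy.

``DataError`` covers malformed or inconsistent user inputs (bad RIS, bad
population files, degenerate record sets); the CLI maps it to exit code 2,
while usage errors (bad flags) exit 1.
"""


class SearchMinerError(Exception):
    """Base class for all package errors."""


class DataError(SearchMinerError):
    """Invalid or inconsistent input data."""


class RISParseError(DataError):
    """Malformed RIS input; carries a line number where possible."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no
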