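"""Exception hierarchy shared across cryoleak modules."""


class CryoleakError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CryoleakError):
    """A table is missing a required column or has an unusable header."""


class TableParseError(CryoleakError):
    """One or more rows of a table failed to parse.

    ``row_errors`` maps 1-based file line numbers (header = line 1) to a
    human-readable description of what went wrong on that line.
    """

    def __init__(self, message: str, row_errors: dict[int, str] | None = None):
        super().__init__(message)
        self.row_errors = dict(row_errors or {})


class DomainError(CryoleakError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateDataError(CryoleakError):
    """Data cannot support the requested computation (flat series, R_max <= R_o, ...)."""
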