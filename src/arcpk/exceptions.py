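"""Exception hierarchy shared across the package.

Everything derives from :class:`ArcPKError` so callers can catch the package's
failures with a single except clause; the finer classes distinguish contract
violations (schema, validation) from statistical/numerical failures.
"""


class ArcPKError(Exception):
    """Base class for all package errors."""


class SchemaError(ArcPKError):
    """An input table is missing a required column or has a bad dtype."""


class ValidationError(ArcPKError):
    """A value violates a domain invariant; carries row-level provenance."""

    def __init__(self, message: str, row: int | None = None, table: str | None = None):
        self.row = row
        self.table = table
        prefix = ""
        if table is not None:
            prefix += f"[{table}"
            prefix += f" row {row}] " if row is not None else "] "
        elif row is not None:
            prefix += f"[row {row}] "
        super().__init__(prefix + message)


class DomainError(ArcPKError):
    """Argument outside the mathematical domain of an operation."""


class InsufficientDataError(ArcPKError):
    """Too few quantifiable observations for the requested computation."""


class DegenerateInputError(ArcPKError):
    """Statistically degenerate input (all-zero differences, zero variance)."""


class FitFailureError(ArcPKError):
    """Both candidate compartmental models failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class LambdaZError(ArcPKError):
    """Terminal slope could not be estimated (non-decaying terminal phase)."""


class IncompleteCollectionError(ArcPKError):
    """Urine collection has a leaked interval; rate/clearance undefined."""


class ConfigError(ArcPKError):
    """Invalid simulation or analysis configuration."""
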