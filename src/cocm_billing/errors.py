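"""Exception types shared across the package."""

from __future__ import annotations

from dataclasses import dataclass


class CocmBillingError(Exception):
    """Base class for all package errors."""


class ConfigError(CocmBillingError):
    """A configuration value is invalid or inconsistent."""


class SchemaError(CocmBillingError):
    """An input file is missing a required column."""


class PricingError(CocmBillingError):
    """A fee schedule is incomplete or invalid for the requested codes."""


@dataclass(frozen=True)
class RowIssue:
    """Row-level diagnostic produced while parsing or validating input rows.

    ``row`` is the 1-based data-row number (header excluded).
    """

    row: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"row {self.row}: {self.message}"


class RegistryValidationError(CocmBillingError):
    """One or more rows failed validation; carries all diagnostics."""

    def __init__(self, issues: list[RowIssue]):
        self.issues = list(issues)
        preview = "; ".join(str(i) for i in self.issues[:5])
        more = f" (+{len(self.issues) - 5} more)" if len(self.issues) > 5 else ""
        super().__init__(f"{len(self.issues)} invalid row(s): {preview}{more}")
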