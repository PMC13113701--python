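"""Exception hierarchy shared across modules.

Grouping errors by kind lets the CLI map them onto distinct exit codes
(validation vs. I/O vs. QC failure).
"""


class StewardbenchError(Exception):
    """Base class for all package errors."""


class ValidationError(StewardbenchError, ValueError):
    """Malformed inputs: bad catalog rows, non-binary outcomes, invalid config."""


class CatalogError(ValidationError):
    """Catalog file violates the agent-record contract."""


class UnmappedAgentError(StewardbenchError, KeyError):
    """A regimen code does not resolve in the catalog."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unmapped agent code: {self.code!r}"


class QCError(StewardbenchError):
    """A quality-control gate failed (e.g. unmapped agents in the cohort)."""


class DegenerateInputError(ValidationError):
    """Statistic undefined for this input (e.g. all-zero deltas for Wilcoxon)."""


class EmptySubsetError(StewardbenchError):
    """An endpoint's evaluability filter selected no admissions."""
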