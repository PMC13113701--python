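"""Antibiotic agent catalog: load, validate, and resolve agent records.

Every downstream mapping (guardrail class flags, AWaRe class, DDD reference,
unit cost) is keyed by agent code through this catalog.  The shipped default
catalog covers ~30 common inpatient agents; it is reference data, not ground
truth, and is fully overridable by a user-supplied file.

Catalog file format: CSV or TSV (sniffed from the extension) with header
columns ``code, display_name, is_carbapenem, is_antipseudomonal, is_anti_mrsa,
aware_class, ddd_ref_g, unit_cost_eur``.  Booleans are ``0``/``1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import CatalogError, UnmappedAgentError

__all__ = [
    "AwareClass",
    "AgentRecord",
    "AgentCatalog",
    "load_catalog",
    "default_catalog",
    "resolve_agent",
    "catalog_qc",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = (
    "code",
    "display_name",
    "is_carbapenem",
    "is_antipseudomonal",
    "is_anti_mrsa",
    "aware_class",
    "ddd_ref_g",
    "unit_cost_eur",
)


class AwareClass(str, enum.Enum):
    """WHO AWaRe stewardship class."""

    ACCESS = "ACCESS"
    WATCH = "WATCH"
    RESERVE = "RESERVE"


#: Numeric AWaRe score used by the AWaRe delta endpoints (monotone in
#: stewardship priority).  Overridable at the endpoint level.
AWARE_SCORES: Mapping[AwareClass, int] = {
    AwareClass.ACCESS: 1,
    AwareClass.WATCH: 2,
    AwareClass.RESERVE: 3,
}


def _normalize_code(code: str) -> str:
    return str(code).strip().upper()


@dataclass(frozen=True)
class AgentRecord:
    """One antibiotic agent with class flags, AWaRe class, DDD and unit cost."""

    code: str
    display_name: str
    is_carbapenem: bool
    is_antipseudomonal: bool
    is_anti_mrsa: bool
    aware_class: AwareClass
    ddd_ref: float  # grams per day, > 0
    unit_cost: float  # EUR per day at DDD, >= 0

    def __post_init__(self) -> None:
        if not self.code or not str(self.code).strip():
            raise CatalogError("agent code must be non-empty")
        if self.ddd_ref <= 0:
            raise CatalogError(f"agent {self.code}: ddd_ref must be > 0, got {self.ddd_ref}")
        if self.unit_cost < 0:
            raise CatalogError(f"agent {self.code}: unit_cost must be >= 0, got {self.unit_cost}")
        # Carbapenems are pharmacologically antipseudomonal but carry only the
        # carbapenem flag here so the two guardrail components stay disjoint.
        if self.is_carbapenem and self.is_antipseudomonal:
            raise CatalogError(
                f"agent {self.code}: is_carbapenem and is_antipseudomonal are mutually exclusive"
            )

    @property
    def aware_score(self) -> int:
        return AWARE_SCORES[self.aware_class]


@dataclass
class AgentCatalog:
    """Collection of :class:`AgentRecord` keyed by canonical code."""

    records: dict[str, AgentRecord] = field(default_factory=dict)
    version_tag: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, code: str) -> bool:
        return _normalize_code(code) in self.records

    def resolve(self, code: str) -> AgentRecord:
        """Return the record for *code* after case-folding and trimming.

        Raises :class:`UnmappedAgentError` on a lookup miss.
        """
        key = _normalize_code(code)
        try:
            return self.records[key]
        except KeyError:
            raise UnmappedAgentError(code) from None

    def add(self, record: AgentRecord) -> None:
        key = _normalize_code(record.code)
        if key in self.records:
            raise CatalogError(f"duplicate agent code: {record.code}")
        self.records[key] = record


def _parse_bool(value: object, row_label: str, column: str) -> bool:
    text = str(value).strip()
    if text in {"0", "1"}:
        return text == "1"
    if isinstance(value, bool):
        return value
    raise CatalogError(f"row {row_label}: column {column!r} must be 0/1, got {value!r}")


def load_catalog(path: str | Path, version_tag: str | None = None) -> AgentCatalog:
    """Load and validate a catalog file (CSV, or TSV for ``.tsv`` paths).

    Raises :class:`CatalogError` naming the offending row for a missing
    column, duplicate code, non-positive DDD, or unknown AWaRe label.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return catalog_from_frame(frame, version_tag=version_tag or path.name)


def catalog_from_frame(frame: pd.DataFrame, version_tag: str = "") -> AgentCatalog:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CatalogError(f"catalog is missing required columns: {missing}")

    catalog = AgentCatalog(version_tag=version_tag)
    for idx, row in frame.iterrows():
        label = f"{idx} (code={row['code']!r})"
        try:
            aware = AwareClass(str(row["aware_class"]).strip().upper())
        except ValueError:
            raise CatalogError(
                f"row {label}: unknown AWaRe label {row['aware_class']!r}"
            ) from None
        try:
            ddd = float(row["ddd_ref_g"])
            cost = float(row["unit_cost_eur"])
        except ValueError:
            raise CatalogError(f"row {label}: non-numeric ddd_ref_g or unit_cost_eur") from None
        try:
            record = AgentRecord(
                code=_normalize_code(row["code"]),
                display_name=str(row["display_name"]),
                is_carbapenem=_parse_bool(row["is_carbapenem"], label, "is_carbapenem"),
                is_antipseudomonal=_parse_bool(
                    row["is_antipseudomonal"], label, "is_antipseudomonal"
                ),
                is_anti_mrsa=_parse_bool(row["is_anti_mrsa"], label, "is_anti_mrsa"),
                aware_class=aware,
                ddd_ref=ddd,
                unit_cost=cost,
            )
            catalog.add(record)
        except CatalogError as exc:
            raise CatalogError(f"row {label}: {exc}") from None
    return catalog


def default_catalog() -> AgentCatalog:
    """The packaged reference catalog (synthetic price list; overridable)."""
    source = resources.files("stewardbench.data").joinpath("default_catalog.csv")
    with resources.as_file(source) as path:
        return load_catalog(path, version_tag="stewardbench-default-v1")


def resolve_agent(catalog: AgentCatalog, code: str) -> AgentRecord:
    """Functional alias for :meth:`AgentCatalog.resolve`."""
    return catalog.resolve(code)


def catalog_qc(cohort: Iterable, catalog: AgentCatalog) -> list[tuple[str, str, str]]:
    """List every (admission_id, arm, code) that does not resolve.

    Report-only: an empty list means the cohort passes mapping QC.  Accepts
    any iterable of objects exposing ``context.admission_id`` and the two
    regimens (``clin_regimen``/``llm_regimen``).
    """
    failures: list[tuple[str, str, str]] = []
    for admission in cohort:
        for arm_name, regimen in (
            ("CLIN", admission.clin_regimen),
            ("LLM", admission.llm_regimen),
        ):
            for code, _dose in regimen.agents:
                if code not in catalog:
                    failures.append((admission.context.admission_id, arm_name, code))
    return failures
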