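"""Cohort readers and writers.

CSV layout: one row per admission.  Regimens are encoded per arm as
semicolon-delimited ``CODE@dose_g`` tokens (order-preserving; blank means
NO_ANTIBIOTIC).  Booleans are ``0``/``1``; a blank boolean cell is treated as
absent and coerced to false under the missing-as-absent rule.  The JSON
format stores the same records as explicit nested objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .guardrails import (
    CONTEXT_BOOL_FIELDS,
    AdmissionContext,
    Arm,
    Regimen,
)
from .endpoints import AdmissionRecord

__all__ = [
    "encode_regimen",
    "decode_regimen",
    "read_cohort",
    "read_cohort_csv",
    "read_cohort_json",
    "write_cohort_csv",
    "write_cohort_json",
]

_CSV_COLUMNS = (
    ["admission_id"]
    + list(CONTEXT_BOOL_FIELDS)
    + [
        "syndrome",
        "age_years",
        "year",
        "clin_regimen",
        "llm_regimen",
        "continued_72h",
        "micro_evaluable",
        "clin_covered",
        "llm_covered",
    ]
)


def encode_regimen(regimen: Regimen) -> str:
    return ";".join(f"{code}@{dose:g}" for code, dose in regimen.agents)


def decode_regimen(text: object, arm: Arm) -> Regimen:
    if text is None or (isinstance(text, float) and pd.isna(text)) or str(text).strip() == "":
        return Regimen(agents=(), arm=arm)
    agents = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        if "@" not in token:
            raise ValidationError(f"regimen token {token!r} is not CODE@dose_g")
        code, dose_text = token.rsplit("@", 1)
        try:
            dose = float(dose_text)
        except ValueError:
            raise ValidationError(f"regimen token {token!r}: bad dose {dose_text!r}") from None
        agents.append((code.strip().upper(), dose))
    return Regimen(agents=tuple(agents), arm=arm)


def _record_from_mapping(raw: dict, substitutions: dict[str, int]) -> AdmissionRecord:
    context = AdmissionContext.from_mapping(raw, substitutions)
    micro = _opt_bool(raw.get("micro_evaluable"))
    clin_cov = _opt_binary(raw.get("clin_covered"))
    llm_cov = _opt_binary(raw.get("llm_covered"))
    if not micro:
        clin_cov = llm_cov = None
    clin = raw.get("clin_regimen")
    llm = raw.get("llm_regimen")
    if isinstance(clin, list):
        clin_reg = Regimen(
            agents=tuple((str(c).upper(), float(d)) for c, d in clin), arm=Arm.CLIN
        )
    else:
        clin_reg = decode_regimen(clin, Arm.CLIN)
    if isinstance(llm, list):
        llm_reg = Regimen(
            agents=tuple((str(c).upper(), float(d)) for c, d in llm), arm=Arm.LLM
        )
    else:
        llm_reg = decode_regimen(llm, Arm.LLM)
    return AdmissionRecord(
        context=context,
        clin_regimen=clin_reg,
        llm_regimen=llm_reg,
        continued_72h=_opt_bool(raw.get("continued_72h")),
        micro_evaluable=micro,
        clin_covered=clin_cov,
        llm_covered=llm_cov,
    )


def _opt_bool(value: object) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return False
    return str(value).strip().lower() in {"1", "true", "yes", "1.0"}


def _opt_binary(value: object) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None
    return int(float(value))


def read_cohort_csv(path: str | Path) -> tuple[list[AdmissionRecord], dict[str, int]]:
    """Read a cohort CSV; returns (records, missing-as-absent substitution counts)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "admission_id" not in frame.columns:
        raise ValidationError("cohort CSV is missing the admission_id column")
    substitutions: dict[str, int] = {}
    records = []
    for _, row in frame.iterrows():
        raw = {k: (None if v == "" else v) for k, v in row.items()}
        records.append(_record_from_mapping(raw, substitutions))
    return records, substitutions


def read_cohort_json(path: str | Path) -> tuple[list[AdmissionRecord], dict[str, int]]:
    with open(path, "r", encoding="utf-8") as handle:
        data = json.load(handle)
    if not isinstance(data, list):
        raise ValidationError("cohort JSON must be a list of admission objects")
    substitutions: dict[str, int] = {}
    records = [_record_from_mapping(raw, substitutions) for raw in data]
    return records, substitutions


def read_cohort(path: str | Path) -> tuple[list[AdmissionRecord], dict[str, int]]:
    """Dispatch on extension: ``.json`` -> JSON, anything else -> CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_cohort_json(path)
    return read_cohort_csv(path)


def _row_from_record(adm: AdmissionRecord) -> dict:
    ctx = adm.context
    row: dict = {"admission_id": ctx.admission_id}
    for name in CONTEXT_BOOL_FIELDS:
        row[name] = int(getattr(ctx, name))
    row["syndrome"] = ctx.syndrome
    row["age_years"] = ctx.age_years
    row["year"] = ctx.year
    row["clin_regimen"] = encode_regimen(adm.clin_regimen)
    row["llm_regimen"] = encode_regimen(adm.llm_regimen)
    row["continued_72h"] = int(adm.continued_72h)
    row["micro_evaluable"] = int(adm.micro_evaluable)
    row["clin_covered"] = "" if adm.clin_covered is None else int(adm.clin_covered)
    row["llm_covered"] = "" if adm.llm_covered is None else int(adm.llm_covered)
    return row


def write_cohort_csv(records: list[AdmissionRecord], path: str | Path) -> None:
    frame = pd.DataFrame([_row_from_record(adm) for adm in records], columns=_CSV_COLUMNS)
    frame.to_csv(path, index=False, lineterminator="\n")


def write_cohort_json(records: list[AdmissionRecord], path: str | Path) -> None:
    rows = []
    for adm in records:
        row = _row_from_record(adm)
        row["clin_regimen"] = [[c, d] for c, d in adm.clin_regimen.agents]
        row["llm_regimen"] = [[c, d] for c, d in adm.llm_regimen.agents]
        row["clin_covered"] = adm.clin_covered
        row["llm_covered"] = adm.llm_covered
        rows.append(row)
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(rows, handle, indent=1)
        handle.write("\n")
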