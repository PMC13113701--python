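"""Prespecified endpoint battery over a paired cohort.

Assembles, in a fixed prespecified order: the primary any-violation
composite, the penalty delta, the three component endpoints, the
broad-spectrum composite, cost deltas at 24 h and in the 72 h
continued-therapy subset, DDD and AWaRe deltas, the microbiology-evaluable
coverage endpoint, concordance counts, the NO_ANTIBIOTIC QC report, and the
Holm-adjusted paired-delta family (m = 6, Wilcoxon p-values).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .catalog import AgentCatalog, catalog_qc
from .errors import EmptySubsetError, QCError, ValidationError
from .guardrails import (
    AdmissionContext,
    GuardrailConfig,
    Regimen,
    Component,
    assess_regimen,
    broad_spectrum_any,
    delta_penalty,
    mdr_risk_proxy,
    severe_proxy,
)
from .stats import (
    MatchedOrResult,
    PairedDeltaSummary,
    PairedTable,
    build_paired_table,
    delta_summary,
    holm_adjust,
    matched_odds_ratio,
)

__all__ = [
    "AdmissionRecord",
    "EndpointResult",
    "ConcordanceSummary",
    "ResultsBundle",
    "CostWindow",
    "HOLM_FAMILY",
    "compute_primary",
    "compute_penalty_endpoint",
    "compute_component_endpoints",
    "compute_broad_spectrum_endpoint",
    "regimen_cost",
    "compute_cost_deltas",
    "regimen_ddd",
    "compute_ddd_endpoint",
    "compute_aware_deltas",
    "compute_coverage_endpoint",
    "compute_concordance",
    "no_antibiotic_qc",
    "run_all",
]

#: Fixed order of the prespecified paired-delta multiplicity family.
HOLM_FAMILY = (
    "delta_penalty",
    "cost_delta_24h",
    "cost_delta_72h",
    "aware_mean_delta",
    "aware_max_delta",
    "ddd_delta_24h",
)


@dataclass(frozen=True)
class AdmissionRecord:
    """One admission: context, the two paired regimens, and evaluability flags."""

    context: AdmissionContext
    clin_regimen: Regimen
    llm_regimen: Regimen
    continued_72h: bool = False
    micro_evaluable: bool = False
    clin_covered: int | None = None
    llm_covered: int | None = None

    def __post_init__(self) -> None:
        if self.micro_evaluable:
            if self.clin_covered is None or self.llm_covered is None:
                raise ValidationError(
                    f"admission {self.context.admission_id}: micro_evaluable requires "
                    "both coverage fields"
                )
        else:
            if self.clin_covered is not None or self.llm_covered is not None:
                raise ValidationError(
                    f"admission {self.context.admission_id}: coverage fields present "
                    "on a non-evaluable admission"
                )


class CostWindow(str, enum.Enum):
    H24 = "H24"
    H72 = "H72"


_WINDOW_DAYS = {CostWindow.H24: 1, CostWindow.H72: 3}


@dataclass
class EndpointResult:
    """One endpoint's denominator, table/summary, and effect estimates."""

    endpoint_id: str
    n: int
    table: PairedTable | None = None
    or_result: MatchedOrResult | None = None
    summary: PairedDeltaSummary | None = None
    arm_rates: tuple[float, float] | None = None  # (clinician, LLM)
    notes: dict = field(default_factory=dict)

    @property
    def computable(self) -> bool:
        return self.n > 0


@dataclass(frozen=True)
class ConcordanceSummary:
    """Set-level agreement between the two arms over the full cohort."""

    n: int
    n_identical_set: int
    n_same_primary_agent: int
    n_any_overlap: int
    n_no_overlap: int


@dataclass
class ResultsBundle:
    """Everything :func:`run_all` produces, serializable to JSON."""

    endpoints: dict[str, EndpointResult]
    holm_family: list[tuple[str, float, float]]  # (endpoint_id, raw_p, adjusted_p)
    concordance: ConcordanceSummary
    qc: dict

    schema_version: str = "stewardbench-bundle-1"

    def to_dict(self) -> dict:
        def _endpoint(e: EndpointResult) -> dict:
            out: dict = {"endpoint_id": e.endpoint_id, "n": e.n}
            if e.table is not None:
                out["table"] = {
                    "n00": e.table.n00,
                    "n01": e.table.n01,
                    "n10": e.table.n10,
                    "n11": e.table.n11,
                }
            if e.or_result is not None:
                out["or"] = {
                    "or_hat": e.or_result.or_hat,
                    "ci_low": e.or_result.ci_low,
                    "ci_high": e.or_result.ci_high,
                    "rd": e.or_result.rd,
                    "p_exact": e.or_result.p_exact,
                }
            if e.summary is not None:
                s = e.summary
                out["delta"] = {
                    "n": s.n,
                    "n_neg": s.n_neg,
                    "n_pos": s.n_pos,
                    "n_zero": s.n_zero,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "mean": s.mean,
                    "sd": s.sd,
                    "p_wilcoxon": s.p_wilcoxon,
                    "p_sign": s.p_sign,
                    "ci_median_low": s.ci_median_low,
                    "ci_median_high": s.ci_median_high,
                }
            if e.arm_rates is not None:
                out["arm_rates"] = {"clin": e.arm_rates[0], "llm": e.arm_rates[1]}
            if e.notes:
                out["notes"] = e.notes
            return out

        return {
            "schema_version": self.schema_version,
            "endpoints": {k: _endpoint(v) for k, v in self.endpoints.items()},
            "holm_family": [
                {"endpoint_id": eid, "p_raw": raw, "p_holm": adj}
                for eid, raw, adj in self.holm_family
            ],
            "concordance": {
                "n": self.concordance.n,
                "n_identical_set": self.concordance.n_identical_set,
                "n_same_primary_agent": self.concordance.n_same_primary_agent,
                "n_any_overlap": self.concordance.n_any_overlap,
                "n_no_overlap": self.concordance.n_no_overlap,
            },
            "qc": self.qc,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def dict_schema_check(cls, data: dict) -> None:
        """Validate the minimal shape of a serialized bundle (for `report`)."""
        if not isinstance(data, dict) or data.get("schema_version") != cls.schema_version:
            raise ValidationError(
                f"unrecognized bundle schema: {data.get('schema_version')!r}"
            )
        if not data.get("endpoints"):
            raise ValidationError("bundle contains no endpoints")

    def summary_table(self) -> pd.DataFrame:
        """Rounded display table (OR/RD to 3 decimals, p to 3 significant figures)."""
        rows = []
        for eid, e in self.endpoints.items():
            row: dict = {"endpoint": eid, "n": e.n}
            if e.table is not None:
                row["n00"], row["n01"], row["n10"], row["n11"] = (
                    e.table.n00,
                    e.table.n01,
                    e.table.n10,
                    e.table.n11,
                )
            if e.arm_rates is not None:
                row["clin_rate"] = round(e.arm_rates[0], 3)
                row["llm_rate"] = round(e.arm_rates[1], 3)
            if e.or_result is not None:
                row["or"] = round(e.or_result.or_hat, 3)
                row["or_ci_low"] = round(e.or_result.ci_low, 3)
                row["or_ci_high"] = round(e.or_result.ci_high, 3)
                row["rd"] = round(e.or_result.rd, 3)
                row["p"] = _sigfig(e.or_result.p_exact, 3)
            if e.summary is not None:
                s = e.summary
                row["median"] = round(s.median, 3)
                row["q1"] = round(s.q1, 3)
                row["q3"] = round(s.q3, 3)
                row["mean"] = round(s.mean, 3)
                row["sd"] = round(s.sd, 3)
                row["p_wilcoxon"] = _sigfig(s.p_wilcoxon, 3)
                row["p_sign"] = _sigfig(s.p_sign, 3)
                if s.ci_median_low is not None:
                    row["median_ci_low"] = round(s.ci_median_low, 3)
                    row["median_ci_high"] = round(s.ci_median_high, 3)
            rows.append(row)
        return pd.DataFrame(rows)


def _sigfig(x: float, digits: int) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{digits}g}")


# ---------------------------------------------------------------------------
# endpoint computations
# ---------------------------------------------------------------------------


def _require_mapped(cohort: Sequence[AdmissionRecord], catalog: AgentCatalog) -> None:
    failures = catalog_qc(cohort, catalog)
    if failures:
        raise QCError(
            f"{len(failures)} unmapped agent codes in cohort; "
            f"first: {failures[0]} — run catalog_qc for the full report"
        )


def _assessments(cohort, cfg, catalog):
    for adm in cohort:
        clin = assess_regimen(adm.clin_regimen, adm.context, cfg, catalog)
        llm = assess_regimen(adm.llm_regimen, adm.context, cfg, catalog)
        yield adm, clin, llm


def _binary_endpoint(endpoint_id: str, pairs: list[tuple[int, int]]) -> EndpointResult:
    table = build_paired_table(pairs)
    result = matched_odds_ratio(table)
    rates = (table.clin_events / table.n, table.llm_events / table.n)
    return EndpointResult(
        endpoint_id=endpoint_id, n=table.n, table=table, or_result=result, arm_rates=rates
    )


def compute_primary(
    cohort: Sequence[AdmissionRecord], cfg: GuardrailConfig, catalog: AgentCatalog
) -> EndpointResult:
    """Primary endpoint: any contextual guardrail violation (paired binary)."""
    _require_mapped(cohort, catalog)
    pairs = [
        (int(clin.any_violation), int(llm.any_violation))
        for _, clin, llm in _assessments(cohort, cfg, catalog)
    ]
    return _binary_endpoint("primary_any_violation", pairs)


def compute_penalty_endpoint(
    cohort: Sequence[AdmissionRecord],
    cfg: GuardrailConfig,
    catalog: AgentCatalog,
    n_boot: int = 5000,
    boot_seed: int = 7,
) -> EndpointResult:
    """Key secondary endpoint: paired penalty delta (LLM - clinician)."""
    _require_mapped(cohort, catalog)
    deltas = [
        delta_penalty(llm, clin) for _, clin, llm in _assessments(cohort, cfg, catalog)
    ]
    summary = delta_summary(deltas, with_bootstrap=True, n_boot=n_boot, seed=boot_seed)
    return EndpointResult(endpoint_id="delta_penalty", n=len(deltas), summary=summary)


_COMPONENT_IDS = {
    Component.CARB: "carb_violation",
    Component.APS: "aps_violation",
    Component.MRSA: "mrsa_violation",
}


def compute_component_endpoints(
    cohort: Sequence[AdmissionRecord], cfg: GuardrailConfig, catalog: AgentCatalog
) -> dict[str, EndpointResult]:
    """One paired-binary endpoint per guardrail component."""
    _require_mapped(cohort, catalog)
    pairs: dict[Component, list[tuple[int, int]]] = {c: [] for c in Component}
    for _, clin, llm in _assessments(cohort, cfg, catalog):
        for comp in Component:
            pairs[comp].append((clin.indicator(comp), llm.indicator(comp)))
    return {
        _COMPONENT_IDS[comp]: _binary_endpoint(_COMPONENT_IDS[comp], pairs[comp])
        for comp in Component
    }


def compute_broad_spectrum_endpoint(
    cohort: Sequence[AdmissionRecord], catalog: AgentCatalog
) -> EndpointResult:
    """Context-free composite: any broad-spectrum class used (paired binary)."""
    _require_mapped(cohort, catalog)
    pairs = [
        (
            int(broad_spectrum_any(adm.clin_regimen, catalog)),
            int(broad_spectrum_any(adm.llm_regimen, catalog)),
        )
        for adm in cohort
    ]
    return _binary_endpoint("broad_spectrum_any", pairs)


def regimen_cost(regimen: Regimen, catalog: AgentCatalog, days: int = 1) -> float:
    """Acquisition cost in EUR: sum of per-day unit costs times window days."""
    return days * sum(catalog.resolve(code).unit_cost for code, _ in regimen.agents)


def compute_cost_deltas(
    cohort: Sequence[AdmissionRecord],
    catalog: AgentCatalog,
    window: CostWindow,
    n_boot: int = 5000,
    boot_seed: int = 7,
) -> EndpointResult:
    """Paired cost delta (LLM - clinician) at 24 h, or 72 h in the continued subset."""
    _require_mapped(cohort, catalog)
    days = _WINDOW_DAYS[window]
    if window is CostWindow.H72:
        subset = [adm for adm in cohort if adm.continued_72h]
        if not subset:
            raise EmptySubsetError(
                "cost_delta_72h: no admissions satisfy continued_72h"
            )
    else:
        subset = list(cohort)
    deltas = [
        regimen_cost(adm.llm_regimen, catalog, days)
        - regimen_cost(adm.clin_regimen, catalog, days)
        for adm in subset
    ]
    summary = delta_summary(deltas, with_bootstrap=True, n_boot=n_boot, seed=boot_seed)
    totals = {
        "clin_total_eur": sum(regimen_cost(a.clin_regimen, catalog, days) for a in subset),
        "llm_total_eur": sum(regimen_cost(a.llm_regimen, catalog, days) for a in subset),
    }
    endpoint_id = "cost_delta_24h" if window is CostWindow.H24 else "cost_delta_72h"
    return EndpointResult(
        endpoint_id=endpoint_id, n=len(subset), summary=summary, notes=totals
    )


def regimen_ddd(regimen: Regimen, catalog: AgentCatalog) -> float:
    """DDD count per 24 h: sum of daily_dose_g / ddd_ref over agents."""
    return sum(dose / catalog.resolve(code).ddd_ref for code, dose in regimen.agents)


def compute_ddd_endpoint(
    cohort: Sequence[AdmissionRecord],
    catalog: AgentCatalog,
    n_boot: int = 5000,
    boot_seed: int = 7,
) -> EndpointResult:
    """Paired DDD/24 h delta (LLM - clinician)."""
    _require_mapped(cohort, catalog)
    deltas = [
        regimen_ddd(adm.llm_regimen, catalog) - regimen_ddd(adm.clin_regimen, catalog)
        for adm in cohort
    ]
    summary = delta_summary(deltas, with_bootstrap=True, n_boot=n_boot, seed=boot_seed)
    return EndpointResult(endpoint_id="ddd_delta_24h", n=len(deltas), summary=summary)


def _aware_scores(regimen: Regimen, catalog: AgentCatalog) -> tuple[float, float]:
    """(mean, max) AWaRe score of a regimen; an empty regimen scores 0 by convention."""
    if regimen.is_empty:
        return 0.0, 0.0
    scores = [catalog.resolve(code).aware_score for code, _ in regimen.agents]
    return sum(scores) / len(scores), float(max(scores))


def compute_aware_deltas(
    cohort: Sequence[AdmissionRecord],
    catalog: AgentCatalog,
    n_boot: int = 5000,
    boot_seed: int = 7,
) -> dict[str, EndpointResult]:
    """Paired AWaRe mean-score and max-score deltas (LLM - clinician)."""
    _require_mapped(cohort, catalog)
    mean_deltas, max_deltas = [], []
    for adm in cohort:
        clin_mean, clin_max = _aware_scores(adm.clin_regimen, catalog)
        llm_mean, llm_max = _aware_scores(adm.llm_regimen, catalog)
        mean_deltas.append(llm_mean - clin_mean)
        max_deltas.append(llm_max - clin_max)
    return {
        "aware_mean_delta": EndpointResult(
            endpoint_id="aware_mean_delta",
            n=len(mean_deltas),
            summary=delta_summary(
                mean_deltas, with_bootstrap=True, n_boot=n_boot, seed=boot_seed
            ),
        ),
        "aware_max_delta": EndpointResult(
            endpoint_id="aware_max_delta",
            n=len(max_deltas),
            summary=delta_summary(
                max_deltas, with_bootstrap=True, n_boot=n_boot, seed=boot_seed
            ),
        ),
    }


def compute_coverage_endpoint(cohort: Sequence[AdmissionRecord]) -> EndpointResult:
    """Paired active coverage within the microbiology-evaluable subset.

    Coverage flags are inputs (adjudication rules are not reconstructible);
    zero evaluable admissions yields a non-computable endpoint, not an error.
    """
    evaluable = [adm for adm in cohort if adm.micro_evaluable]
    n_non_evaluable = len(cohort) - len(evaluable)
    if not evaluable:
        return EndpointResult(
            endpoint_id="coverage_micro_evaluable",
            n=0,
            notes={"n_non_evaluable": n_non_evaluable, "status": "not computable"},
        )
    pairs = [(adm.clin_covered, adm.llm_covered) for adm in evaluable]
    result = _binary_endpoint("coverage_micro_evaluable", pairs)
    result.notes["n_non_evaluable"] = n_non_evaluable
    return result


def _code_set(regimen: Regimen) -> frozenset[str]:
    return frozenset(code.strip().upper() for code, _ in regimen.agents)


def compute_concordance(cohort: Sequence[AdmissionRecord]) -> ConcordanceSummary:
    """Set-level agreement: identical sets, same primary agent, any overlap.

    The primary agent is the first-listed agent of each regimen (order is
    preserved from the source data).  "Identical" requires equal, non-empty
    sets so it stays a subset of "any overlap".
    """
    n_identical = n_primary = n_overlap = 0
    for adm in cohort:
        clin, llm = _code_set(adm.clin_regimen), _code_set(adm.llm_regimen)
        if clin & llm:
            n_overlap += 1
            if clin == llm:
                n_identical += 1
        if (
            not adm.clin_regimen.is_empty
            and not adm.llm_regimen.is_empty
            and adm.clin_regimen.codes[0].strip().upper()
            == adm.llm_regimen.codes[0].strip().upper()
        ):
            n_primary += 1
    return ConcordanceSummary(
        n=len(cohort),
        n_identical_set=n_identical,
        n_same_primary_agent=n_primary,
        n_any_overlap=n_overlap,
        n_no_overlap=len(cohort) - n_overlap,
    )


def no_antibiotic_qc(
    cohort: Sequence[AdmissionRecord], cfg: GuardrailConfig
) -> list[dict]:
    """Rows for every admission whose LLM regimen is empty, with proxy values.

    A row is flagged when its SEVERE or MDR_RISK proxy is true: an empty
    recommendation then contradicts the structured trigger pattern.
    """
    report = []
    for adm in cohort:
        if adm.llm_regimen.is_empty:
            severe = severe_proxy(adm.context)
            mdr = mdr_risk_proxy(adm.context)
            report.append(
                {
                    "admission_id": adm.context.admission_id,
                    "severe": severe,
                    "mdr_risk": mdr,
                    "flagged": severe or mdr,
                }
            )
    return report


def run_all(
    cohort: Sequence[AdmissionRecord],
    cfg: GuardrailConfig,
    catalog: AgentCatalog,
    n_boot: int = 5000,
    boot_seed: int = 7,
) -> ResultsBundle:
    """Execute the full prespecified endpoint battery over the cohort."""
    qc_failures = catalog_qc(cohort, catalog)
    if qc_failures:
        raise QCError(
            f"catalog QC failed: {len(qc_failures)} unmapped (admission, arm, code) "
            f"entries; first: {qc_failures[0]}"
        )

    endpoints: dict[str, EndpointResult] = {}
    endpoints["primary_any_violation"] = compute_primary(cohort, cfg, catalog)
    endpoints["delta_penalty"] = compute_penalty_endpoint(
        cohort, cfg, catalog, n_boot=n_boot, boot_seed=boot_seed
    )
    endpoints.update(compute_component_endpoints(cohort, cfg, catalog))
    endpoints["broad_spectrum_any"] = compute_broad_spectrum_endpoint(cohort, catalog)
    endpoints["cost_delta_24h"] = compute_cost_deltas(
        cohort, catalog, CostWindow.H24, n_boot=n_boot, boot_seed=boot_seed
    )
    try:
        endpoints["cost_delta_72h"] = compute_cost_deltas(
            cohort, catalog, CostWindow.H72, n_boot=n_boot, boot_seed=boot_seed
        )
    except EmptySubsetError:
        endpoints["cost_delta_72h"] = EndpointResult(
            endpoint_id="cost_delta_72h", n=0, notes={"status": "empty subset"}
        )
    endpoints["ddd_delta_24h"] = compute_ddd_endpoint(
        cohort, catalog, n_boot=n_boot, boot_seed=boot_seed
    )
    endpoints.update(
        compute_aware_deltas(cohort, catalog, n_boot=n_boot, boot_seed=boot_seed)
    )
    endpoints["coverage_micro_evaluable"] = compute_coverage_endpoint(cohort)

    concordance = compute_concordance(cohort)
    qc = {
        "catalog_qc": qc_failures,
        "no_antibiotic": no_antibiotic_qc(cohort, cfg),
    }

    family_ps = []
    for eid in HOLM_FAMILY:
        endpoint = endpoints.get(eid)
        if endpoint is not None and endpoint.summary is not None:
            family_ps.append(endpoint.summary.p_wilcoxon)
        else:
            family_ps.append(1.0)  # non-computable member carries no evidence
    adjusted = holm_adjust(family_ps)
    holm_family = [
        (eid, raw, adj) for eid, raw, adj in zip(HOLM_FAMILY, family_ps, adjusted)
    ]

    return ResultsBundle(
        endpoints=endpoints, holm_family=holm_family, concordance=concordance, qc=qc
    )
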