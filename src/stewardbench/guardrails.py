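"""Contextual guardrail engine.

Computes the justification proxies (SEVERE, MDR_RISK, PRIOR_MRSA), the three
per-component contextual violation indicators, the any-violation flag, and
the weighted guardrail penalty for a regimen:

    penalty = w_carb * I_carb + w_aps * I_aps + w_mrsa * I_mrsa

with default weights 2 / 1 / 1.  A component is violated when the regimen
uses an agent of that class and the component's justification rule evaluates
false on the admission context.  Justification rules are user-configurable
Boolean expressions over the fixed proxy vocabulary
``{SEVERE, MDR_RISK, PRIOR_MRSA}``.
"""

from __future__ import annotations

import ast
import enum
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .catalog import AgentCatalog
from .errors import ValidationError

__all__ = [
    "AdmissionContext",
    "Regimen",
    "Component",
    "GuardrailConfig",
    "GuardrailAssessment",
    "severe_proxy",
    "mdr_risk_proxy",
    "proxy_values",
    "component_violation",
    "assess_regimen",
    "delta_penalty",
    "broad_spectrum_any",
]

SEVERE_FIELDS = (
    "icu_24h",
    "septic_shock",
    "vasopressors",
    "mechanical_ventilation",
    "respiratory_failure",
)

MDR_RISK_FIELDS = (
    "prior_esbl_cre_vre",
    "abx_prior_90d",
    "hosp_prior_90d",
    "ltcf_resident",
    "healthcare_associated",
)

CONTEXT_BOOL_FIELDS = SEVERE_FIELDS + MDR_RISK_FIELDS + (
    "prior_mrsa_colonization",
    "sepsis_documented",
    "female",
)


@dataclass(frozen=True)
class AdmissionContext:
    """Structured de-identified context flags for one admission.

    All booleans default to ``False``: absence of documentation is treated as
    absence of the condition (missing-as-absent).  Use
    :meth:`from_mapping` when ingesting raw records so the substitutions are
    counted and can be logged.
    """

    admission_id: str
    icu_24h: bool = False
    septic_shock: bool = False
    vasopressors: bool = False
    mechanical_ventilation: bool = False
    respiratory_failure: bool = False
    prior_esbl_cre_vre: bool = False
    abx_prior_90d: bool = False
    hosp_prior_90d: bool = False
    ltcf_resident: bool = False
    healthcare_associated: bool = False
    prior_mrsa_colonization: bool = False
    sepsis_documented: bool = False
    syndrome: str = ""
    age_years: int = 0
    female: bool = False
    year: int = 0

    @classmethod
    def from_mapping(
        cls, record: Mapping[str, object], substitutions: dict[str, int] | None = None
    ) -> "AdmissionContext":
        """Build a context from a raw mapping, applying missing-as-absent.

        A boolean field that is absent, blank, or None is coerced to False;
        when *substitutions* is given, the per-field substitution count is
        incremented so ingestion can log the rule transparently.
        """
        kwargs: dict[str, object] = {"admission_id": str(record["admission_id"])}
        for name in CONTEXT_BOOL_FIELDS:
            raw = record.get(name)
            if raw is None or raw == "":
                kwargs[name] = False
                if substitutions is not None:
                    substitutions[name] = substitutions.get(name, 0) + 1
            else:
                kwargs[name] = _coerce_bool(raw, name)
        kwargs["syndrome"] = str(record.get("syndrome", "") or "")
        kwargs["age_years"] = int(record.get("age_years", 0) or 0)
        kwargs["year"] = int(record.get("year", 0) or 0)
        return cls(**kwargs)  # type: ignore[arg-type]


def _coerce_bool(value: object, name: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "yes"}:
        return True
    if text in {"0", "false", "no"}:
        return False
    raise ValidationError(f"field {name!r}: cannot interpret {value!r} as boolean")


class Arm(str, enum.Enum):
    CLIN = "CLIN"
    LLM = "LLM"


@dataclass(frozen=True)
class Regimen:
    """A set of concurrently initiated systemic agents with daily doses.

    ``agents`` preserves input order (the first-listed agent is the primary
    agent for concordance purposes); an empty tuple encodes NO_ANTIBIOTIC.
    """

    agents: tuple[tuple[str, float], ...] = ()
    arm: Arm = Arm.CLIN

    def __post_init__(self) -> None:
        codes = [code for code, _ in self.agents]
        if len(codes) != len(set(codes)):
            raise ValidationError(f"duplicate agent code within regimen: {codes}")
        for code, dose in self.agents:
            if dose <= 0:
                raise ValidationError(f"agent {code}: daily_dose_g must be > 0, got {dose}")

    @property
    def is_empty(self) -> bool:
        return not self.agents

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(code for code, _ in self.agents)


class Component(str, enum.Enum):
    """The three guardrail components."""

    CARB = "CARB"
    APS = "APS"
    MRSA = "MRSA"


_CLASS_FLAG = {
    Component.CARB: "is_carbapenem",
    Component.APS: "is_antipseudomonal",
    Component.MRSA: "is_anti_mrsa",
}

_PROXY_NAMES = frozenset({"SEVERE", "MDR_RISK", "PRIOR_MRSA"})
_ALLOWED_NODES = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.Name,
    ast.Load,
)


def compile_rule(expression: str):
    """Compile a justification-rule expression over the proxy vocabulary.

    Only ``and``/``or``/``not``, parentheses, and the names SEVERE, MDR_RISK,
    PRIOR_MRSA are allowed; anything else is a validation error.
    """
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ValidationError(f"cannot parse rule {expression!r}: {exc}") from None
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ValidationError(
                f"rule {expression!r}: disallowed syntax {type(node).__name__}"
            )
        if isinstance(node, ast.Name) and node.id not in _PROXY_NAMES:
            raise ValidationError(
                f"rule {expression!r}: unknown proxy name {node.id!r} "
                f"(allowed: {sorted(_PROXY_NAMES)})"
            )
    return compile(tree, "<guardrail-rule>", "eval")


DEFAULT_WEIGHTS: Mapping[Component, int] = {
    Component.CARB: 2,
    Component.APS: 1,
    Component.MRSA: 1,
}

# Appendix-level Boolean logic is not available; these defaults follow the
# named justification domains and are fully user-configurable.
DEFAULT_RULES: Mapping[Component, str] = {
    Component.CARB: "SEVERE or MDR_RISK",
    Component.APS: "SEVERE or MDR_RISK",
    Component.MRSA: "PRIOR_MRSA",
}


@dataclass
class GuardrailConfig:
    """Weights and justification rules for the three components."""

    weights: dict[Component, int] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    justification_rules: dict[Component, str] = field(
        default_factory=lambda: dict(DEFAULT_RULES)
    )

    def __post_init__(self) -> None:
        for comp in Component:
            if comp not in self.weights:
                raise ValidationError(f"missing weight for component {comp.value}")
            if self.weights[comp] <= 0:
                raise ValidationError(
                    f"weight for {comp.value} must be strictly positive, got {self.weights[comp]}"
                )
            if comp not in self.justification_rules:
                raise ValidationError(f"missing justification rule for component {comp.value}")
        self._compiled = {
            comp: compile_rule(rule) for comp, rule in self.justification_rules.items()
        }

    def justified(self, component: Component, proxies: Mapping[str, bool]) -> bool:
        env = {"__builtins__": {}}
        return bool(eval(self._compiled[component], env, dict(proxies)))  # noqa: S307

    # --- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": {comp.value: w for comp, w in self.weights.items()},
            "justification_rules": {
                comp.value: rule for comp, rule in self.justification_rules.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "GuardrailConfig":
        weights = dict(DEFAULT_WEIGHTS)
        rules = dict(DEFAULT_RULES)
        for key, value in (data.get("weights") or {}).items():
            weights[Component(key)] = int(value)
        for key, value in (data.get("justification_rules") or {}).items():
            rules[Component(key)] = str(value)
        return cls(weights=weights, justification_rules=rules)

    @classmethod
    def from_file(cls, path) -> "GuardrailConfig":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)


@dataclass(frozen=True)
class GuardrailAssessment:
    """Per-regimen component indicators, any-violation flag, and penalty."""

    i_carb: int
    i_aps: int
    i_mrsa: int
    any_violation: bool
    penalty: int

    def indicator(self, component: Component) -> int:
        return {
            Component.CARB: self.i_carb,
            Component.APS: self.i_aps,
            Component.MRSA: self.i_mrsa,
        }[component]


def severe_proxy(ctx: AdmissionContext) -> bool:
    """Early-severity proxy: any of the five severity/support flags."""
    return any(getattr(ctx, name) for name in SEVERE_FIELDS)


def mdr_risk_proxy(ctx: AdmissionContext) -> bool:
    """MDR-risk proxy: any of the five history/setting flags."""
    return any(getattr(ctx, name) for name in MDR_RISK_FIELDS)


def proxy_values(ctx: AdmissionContext) -> dict[str, bool]:
    return {
        "SEVERE": severe_proxy(ctx),
        "MDR_RISK": mdr_risk_proxy(ctx),
        "PRIOR_MRSA": ctx.prior_mrsa_colonization,
    }


def _uses_class(regimen: Regimen, component: Component, catalog: AgentCatalog) -> bool:
    flag = _CLASS_FLAG[component]
    return any(getattr(catalog.resolve(code), flag) for code, _ in regimen.agents)


def component_violation(
    regimen: Regimen,
    ctx: AdmissionContext,
    component: Component,
    cfg: GuardrailConfig,
    catalog: AgentCatalog,
) -> int:
    """1 iff the regimen uses the component's class without justification."""
    if not _uses_class(regimen, component, catalog):
        return 0
    return 0 if cfg.justified(component, proxy_values(ctx)) else 1


def assess_regimen(
    regimen: Regimen,
    ctx: AdmissionContext,
    cfg: GuardrailConfig,
    catalog: AgentCatalog,
) -> GuardrailAssessment:
    """Full guardrail assessment of one regimen against its context."""
    i_carb = component_violation(regimen, ctx, Component.CARB, cfg, catalog)
    i_aps = component_violation(regimen, ctx, Component.APS, cfg, catalog)
    i_mrsa = component_violation(regimen, ctx, Component.MRSA, cfg, catalog)
    penalty = (
        cfg.weights[Component.CARB] * i_carb
        + cfg.weights[Component.APS] * i_aps
        + cfg.weights[Component.MRSA] * i_mrsa
    )
    return GuardrailAssessment(
        i_carb=i_carb,
        i_aps=i_aps,
        i_mrsa=i_mrsa,
        any_violation=(i_carb + i_aps + i_mrsa) >= 1,
        penalty=penalty,
    )


def delta_penalty(llm: GuardrailAssessment, clin: GuardrailAssessment) -> int:
    """Paired penalty delta, LLM minus clinician (negative favors LLM)."""
    return llm.penalty - clin.penalty


def broad_spectrum_any(regimen: Regimen, catalog: AgentCatalog) -> bool:
    """Context-free composite: any carbapenem, antipseudomonal, or anti-MRSA agent."""
    return any(_uses_class(regimen, comp, catalog) for comp in Component)
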