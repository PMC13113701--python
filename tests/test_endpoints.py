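import pytest

from stewardbench import (
    AdmissionContext,
    AdmissionRecord,
    CostWindow,
    EmptySubsetError,
    GuardrailConfig,
    QCError,
    Regimen,
    ValidationError,
    run_all,
)
from stewardbench.catalog import catalog_from_frame
from stewardbench.endpoints import (
    HOLM_FAMILY,
    compute_aware_deltas,
    compute_broad_spectrum_endpoint,
    compute_component_endpoints,
    compute_concordance,
    compute_cost_deltas,
    compute_coverage_endpoint,
    compute_penalty_endpoint,
    compute_primary,
    no_antibiotic_qc,
    regimen_cost,
    regimen_ddd,
)
from stewardbench.guardrails import Arm

import pandas as pd


def admission(
    clin=(),
    llm=(),
    admission_id="A1",
    continued=False,
    micro=False,
    clin_cov=None,
    llm_cov=None,
    **ctx_flags,
):
    return AdmissionRecord(
        context=AdmissionContext(admission_id=admission_id, **ctx_flags),
        clin_regimen=Regimen(tuple(clin), Arm.CLIN),
        llm_regimen=Regimen(tuple(llm), Arm.LLM),
        continued_72h=continued,
        micro_evaluable=micro,
        clin_covered=clin_cov,
        llm_covered=llm_cov,
    )


CARB = ("MEROPENEM", 3.0)
NARROW = ("AMOXICILLIN", 1.5)


class TestPrimary:
    def test_single_clin_violation(self, cfg, catalog):
        cohort = [admission(clin=[CARB], llm=[NARROW])]
        endpoint = compute_primary(cohort, cfg, catalog)
        t = endpoint.table
        assert (t.n00, t.n01, t.n10, t.n11) == (0, 0, 1, 0)

    def test_fully_concordant_violations(self, cfg, catalog):
        cohort = [admission(clin=[CARB], llm=[CARB], admission_id=f"A{i}") for i in range(4)]
        endpoint = compute_primary(cohort, cfg, catalog)
        assert endpoint.or_result.or_hat == 1.0
        assert endpoint.or_result.p_exact == 1.0

    def test_unmapped_agent_aborts(self, cfg, catalog):
        cohort = [admission(clin=[("NOTADRUG", 1.0)])]
        with pytest.raises(QCError, match="unmapped"):
            compute_primary(cohort, cfg, catalog)

    def test_arm_rates_match_table(self, cfg, catalog):
        cohort = [
            admission(clin=[CARB], llm=[NARROW], admission_id="A1"),
            admission(clin=[NARROW], llm=[CARB], admission_id="A2"),
            admission(clin=[NARROW], llm=[NARROW], admission_id="A3"),
        ]
        endpoint = compute_primary(cohort, cfg, catalog)
        clin_rate = sum(
            1 for adm in cohort if adm.clin_regimen.codes and adm.clin_regimen.codes[0] == "MEROPENEM"
        ) / len(cohort)
        assert endpoint.arm_rates[0] == pytest.approx(clin_rate)


class TestPenaltyEndpoint:
    def test_identical_arms_all_zero(self, cfg, catalog):
        cohort = [admission(clin=[CARB], llm=[CARB], admission_id=f"A{i}") for i in range(3)]
        endpoint = compute_penalty_endpoint(cohort, cfg, catalog, n_boot=100)
        assert endpoint.summary.n_zero == 3
        assert endpoint.summary.p_sign == 1.0

    def test_sign_consistency_with_primary(self, cfg, catalog, fixture_cohort):
        from stewardbench.guardrails import assess_regimen, delta_penalty

        for adm in fixture_cohort[:120]:
            clin = assess_regimen(adm.clin_regimen, adm.context, cfg, catalog)
            llm = assess_regimen(adm.llm_regimen, adm.context, cfg, catalog)
            if delta_penalty(llm, clin) < 0:
                assert clin.penalty > llm.penalty
                assert clin.any_violation


class TestComponentEndpoints:
    def test_component_never_used(self, cfg, catalog):
        cohort = [admission(clin=[NARROW], llm=[NARROW], admission_id=f"A{i}") for i in range(5)]
        endpoints = compute_component_endpoints(cohort, cfg, catalog)
        carb = endpoints["carb_violation"]
        assert (carb.table.n00, carb.table.n01, carb.table.n10, carb.table.n11) == (5, 0, 0, 0)
        assert carb.or_result.p_exact == 1.0

    def test_three_endpoints_returned(self, cfg, catalog):
        endpoints = compute_component_endpoints([admission(clin=[CARB])], cfg, catalog)
        assert set(endpoints) == {"carb_violation", "aps_violation", "mrsa_violation"}


class TestBroadSpectrum:
    def test_all_narrow(self, cfg, catalog):
        cohort = [admission(clin=[NARROW], llm=[NARROW])]
        endpoint = compute_broad_spectrum_endpoint(cohort, catalog)
        assert endpoint.arm_rates == (0.0, 0.0)

    def test_context_does_not_matter(self, cfg, catalog):
        cohort = [admission(clin=[CARB], llm=[NARROW], icu_24h=True)]
        endpoint = compute_broad_spectrum_endpoint(cohort, catalog)
        assert endpoint.table.n10 == 1


def toy_catalog():
    frame = pd.DataFrame(
        [
            {
                "code": "A",
                "display_name": "a",
                "is_carbapenem": 0,
                "is_antipseudomonal": 0,
                "is_anti_mrsa": 0,
                "aware_class": "ACCESS",
                "ddd_ref_g": 2.0,
                "unit_cost_eur": 10.0,
            },
            {
                "code": "B",
                "display_name": "b",
                "is_carbapenem": 0,
                "is_antipseudomonal": 0,
                "is_anti_mrsa": 0,
                "aware_class": "RESERVE",
                "ddd_ref_g": 1.0,
                "unit_cost_eur": 4.0,
            },
        ]
    )
    return catalog_from_frame(frame, version_tag="toy")


class TestCosts:
    def test_empty_regimen_costs_nothing(self, catalog):
        assert regimen_cost(Regimen((), Arm.CLIN), catalog) == 0.0

    def test_single_agent_24h(self):
        cat = toy_catalog()
        assert regimen_cost(Regimen((("A", 2.0),), Arm.CLIN), cat) == 10.0

    def test_two_agents_72h(self):
        cat = toy_catalog()
        reg = Regimen((("A", 2.0), ("B", 1.0)), Arm.CLIN)
        assert regimen_cost(reg, cat, days=3) == 3 * (10.0 + 4.0)

    def test_toy_median_delta(self):
        cat = toy_catalog()
        cohort = [
            admission(clin=[("A", 2.0)], llm=[("B", 1.0)], admission_id="A1"),
            admission(clin=[("A", 2.0)], llm=[("B", 1.0)], admission_id="A2"),
        ]
        endpoint = compute_cost_deltas(cohort, cat, CostWindow.H24, n_boot=50)
        assert endpoint.summary.median == -6.0

    def test_identical_regimens_zero_deltas(self):
        cat = toy_catalog()
        cohort = [admission(clin=[("A", 2.0)], llm=[("A", 2.0)])]
        endpoint = compute_cost_deltas(cohort, cat, CostWindow.H24, n_boot=50)
        assert endpoint.summary.n_zero == 1

    def test_empty_continuation_subset_errors(self):
        cat = toy_catalog()
        cohort = [admission(clin=[("A", 2.0)], llm=[("B", 1.0)], continued=False)]
        with pytest.raises(EmptySubsetError, match="continued_72h"):
            compute_cost_deltas(cohort, cat, CostWindow.H72)

    def test_h72_uses_subset_denominator(self):
        cat = toy_catalog()
        cohort = [
            admission(clin=[("A", 2.0)], llm=[("B", 1.0)], continued=True, admission_id="A1"),
            admission(clin=[("A", 2.0)], llm=[("B", 1.0)], continued=False, admission_id="A2"),
        ]
        endpoint = compute_cost_deltas(cohort, cat, CostWindow.H72, n_boot=50)
        assert endpoint.n == 1
        assert endpoint.summary.median == -18.0


class TestDDD:
    def test_empty_regimen(self, catalog):
        assert regimen_ddd(Regimen((), Arm.CLIN), catalog) == 0.0

    def test_dose_at_reference_is_one(self, catalog):
        assert regimen_ddd(Regimen((("MEROPENEM", 3.0),), Arm.CLIN), catalog) == pytest.approx(1.0)

    def test_two_agents_at_half_reference(self):
        cat = toy_catalog()
        reg = Regimen((("A", 1.0), ("B", 0.5)), Arm.CLIN)
        assert regimen_ddd(reg, cat) == pytest.approx(1.0)


class TestAware:
    def test_single_access_agent(self):
        cat = toy_catalog()
        cohort = [admission(clin=[("A", 2.0)], llm=[("A", 2.0), ("B", 1.0)])]
        endpoints = compute_aware_deltas(cohort, cat, n_boot=50)
        # clin: mean 1 max 1; llm: mean 2 max 3
        assert endpoints["aware_mean_delta"].summary.mean == pytest.approx(1.0)
        assert endpoints["aware_max_delta"].summary.mean == pytest.approx(2.0)

    def test_identical_arms_zero(self):
        cat = toy_catalog()
        cohort = [admission(clin=[("B", 1.0)], llm=[("B", 1.0)])]
        endpoints = compute_aware_deltas(cohort, cat, n_boot=50)
        assert endpoints["aware_mean_delta"].summary.n_zero == 1
        assert endpoints["aware_max_delta"].summary.n_zero == 1

    def test_empty_regimen_scores_zero(self):
        cat = toy_catalog()
        cohort = [admission(clin=[("A", 2.0)], llm=[])]
        endpoints = compute_aware_deltas(cohort, cat, n_boot=50)
        assert endpoints["aware_mean_delta"].summary.mean == pytest.approx(-1.0)


class TestCoverage:
    def test_zero_evaluable_not_an_error(self):
        endpoint = compute_coverage_endpoint([admission()])
        assert endpoint.n == 0
        assert not endpoint.computable
        assert endpoint.notes["status"] == "not computable"

    def test_missing_coverage_field_is_invariant_error(self):
        with pytest.raises(ValidationError, match="coverage"):
            admission(micro=True, clin_cov=1, llm_cov=None)

    def test_coverage_on_non_evaluable_rejected(self):
        with pytest.raises(ValidationError):
            admission(micro=False, clin_cov=1, llm_cov=0)

    def test_subset_table(self):
        cohort = [
            admission(micro=True, clin_cov=1, llm_cov=0, admission_id="A1"),
            admission(micro=True, clin_cov=0, llm_cov=1, admission_id="A2"),
            admission(admission_id="A3"),
        ]
        endpoint = compute_coverage_endpoint(cohort)
        assert endpoint.n == 2
        assert endpoint.notes["n_non_evaluable"] == 1
        assert (endpoint.table.n01, endpoint.table.n10) == (1, 1)


class TestConcordance:
    def test_identical_sets_counted_everywhere(self):
        cohort = [admission(clin=[CARB], llm=[CARB])]
        summary = compute_concordance(cohort)
        assert summary.n_identical_set == 1
        assert summary.n_same_primary_agent == 1
        assert summary.n_any_overlap == 1
        assert summary.n_no_overlap == 0

    def test_disjoint_nonempty_sets(self):
        cohort = [admission(clin=[CARB], llm=[NARROW])]
        summary = compute_concordance(cohort)
        assert summary.n_any_overlap == 0
        assert summary.n_no_overlap == 1

    def test_same_primary_different_set(self):
        cohort = [admission(clin=[CARB, NARROW], llm=[CARB])]
        summary = compute_concordance(cohort)
        assert summary.n_identical_set == 0
        assert summary.n_same_primary_agent == 1
        assert summary.n_any_overlap == 1

    def test_counts_partition(self, fixture_cohort):
        summary = compute_concordance(fixture_cohort)
        assert summary.n_any_overlap + summary.n_no_overlap == summary.n
        assert summary.n_identical_set <= summary.n_any_overlap


class TestNoAntibioticQC:
    def test_empty_llm_with_severe_is_flagged(self, cfg):
        cohort = [admission(clin=[CARB], llm=[], icu_24h=True)]
        report = no_antibiotic_qc(cohort, cfg)
        assert len(report) == 1
        assert report[0]["flagged"]

    def test_no_empty_regimens(self, cfg):
        assert no_antibiotic_qc([admission(clin=[CARB], llm=[NARROW])], cfg) == []

    def test_quiet_empty_llm_not_flagged(self, cfg):
        report = no_antibiotic_qc([admission(clin=[CARB], llm=[])], cfg)
        assert report == [
            {"admission_id": "A1", "severe": False, "mdr_risk": False, "flagged": False}
        ]


class TestRunAll:
    def test_identical_arms_cohort(self, cfg, catalog):
        cohort = [
            admission(clin=[CARB], llm=[CARB], continued=True, admission_id=f"A{i}")
            for i in range(6)
        ]
        bundle = run_all(cohort, cfg, catalog, n_boot=50)
        for eid in ("primary_any_violation", "broad_spectrum_any"):
            assert bundle.endpoints[eid].or_result.or_hat == 1.0
        for eid in HOLM_FAMILY:
            summary = bundle.endpoints[eid].summary
            assert summary.n_zero == summary.n

    def test_holm_family_has_six_members(self, fixture_bundle):
        assert len(fixture_bundle.holm_family) == 6
        assert [eid for eid, _, _ in fixture_bundle.holm_family] == list(HOLM_FAMILY)

    def test_holm_monotone_in_raw_order(self, fixture_bundle):
        entries = sorted(fixture_bundle.holm_family, key=lambda e: e[1])
        adjusted = [e[2] for e in entries]
        assert adjusted == sorted(adjusted)

    def test_qc_failure_aborts(self, cfg, catalog):
        cohort = [admission(clin=[("NOTADRUG", 1.0)])]
        with pytest.raises(QCError):
            run_all(cohort, cfg, catalog)

    def test_arm_rates_reconstructed_from_tables(self, fixture_bundle):
        for eid in (
            "primary_any_violation",
            "carb_violation",
            "aps_violation",
            "mrsa_violation",
            "broad_spectrum_any",
        ):
            endpoint = fixture_bundle.endpoints[eid]
            t = endpoint.table
            assert endpoint.arm_rates[0] == pytest.approx((t.n10 + t.n11) / t.n)
            assert endpoint.arm_rates[1] == pytest.approx((t.n01 + t.n11) / t.n)

    def test_denominators_reflect_filters(self, fixture_bundle):
        assert fixture_bundle.endpoints["cost_delta_72h"].n == 323
        assert fixture_bundle.endpoints["coverage_micro_evaluable"].n == 158
        assert fixture_bundle.endpoints["primary_any_violation"].n == 493

    def test_bundle_roundtrips_to_json(self, fixture_bundle):
        import json

        data = json.loads(fixture_bundle.to_json())
        assert data["endpoints"]["primary_any_violation"]["table"]["n10"] == 76
        assert len(data["holm_family"]) == 6

    def test_summary_table_shape(self, fixture_bundle):
        frame = fixture_bundle.summary_table()
        assert "endpoint" in frame.columns
        assert len(frame) == len(fixture_bundle.endpoints)
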