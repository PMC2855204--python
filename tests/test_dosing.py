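import pytest
from hypothesis import given, settings, strategies as st

import neodose as nd
from neodose.dosing import (
    ALLOWED_INTERVALS,
    KnowledgeBaseError,
    severity_category,
)


def make_state(**kw):
    defaults = dict(
        patient_id="P0", postnatal_age=7, gestational_age=38,
        weight=3000, estimated_gfr=40.0, diagnosis="sepsis",
    )
    defaults.update(kw)
    return nd.PatientState(**defaults)


def make_rule(**kw):
    defaults = dict(
        drug="ampicillin", pharmaceutical_form="vial", indication="any",
        ga_band=(22, 44), pna_band=(0, 365),
        recommended_dose_per_kg=50, recommended_interval=12, tolerance=0.10,
    )
    defaults.update(kw)
    return nd.DoseRule(**defaults)


class TestEstimateGfr:
    @pytest.mark.parametrize(
        "length, scr, maturity, k_kwargs, expected",
        [
            (50, 0.5, "term", {"k_term": 0.45}, 45.0),
            (40, 1.0, "preterm", {"k_preterm": 0.33}, 13.2),
        ],
    )
    def test_schwartz_form(self, length, scr, maturity, k_kwargs, expected):
        assert nd.estimate_gfr(length, scr, maturity, **k_kwargs) == pytest.approx(expected)

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(ValueError):
            nd.estimate_gfr(50, 0.0)


class TestPatientState:
    @pytest.mark.parametrize(
        "field, value",
        [("gestational_age", 21), ("gestational_age", 45),
         ("postnatal_age", -1), ("weight", 0), ("estimated_gfr", -5)],
    )
    def test_invariants_enforced(self, field, value):
        with pytest.raises(ValueError):
            make_state(**{field: value})


class TestKnowledgeBase:
    def test_packaged_kb_loads_with_antibiotics_and_anticonvulsants(self, kb):
        assert {"ampicillin", "gentamicin", "phenobarbital"} <= set(kb.drugs)

    def test_match_returns_containing_rule(self, kb):
        state = make_state(postnatal_age=3)
        rule = kb.match(state, "ampicillin")
        assert rule is not None
        assert rule.pna_band == (0, 7)
        assert rule.recommended_interval == 12

    def test_unlisted_drug_matches_nothing(self, kb):
        assert kb.match(make_state(), "vancomycin") is None

    def test_specific_indication_shadows_wildcard(self, kb):
        state = make_state(postnatal_age=3, diagnosis="meningitis")
        rule = kb.match(state, "ampicillin")
        assert rule.indication == "meningitis"
        assert rule.recommended_dose_per_kg == 100

    def test_gfr_bands_partition(self, kb):
        low = make_state(estimated_gfr=10.0)
        high = make_state(estimated_gfr=40.0)
        assert kb.match(low, "gentamicin").recommended_interval == 48
        assert kb.match(high, "gentamicin").recommended_interval == 24

    def test_overlapping_rules_rejected_at_load(self):
        a = make_rule(pna_band=(0, 10))
        b = make_rule(pna_band=(5, 20))
        with pytest.raises(KnowledgeBaseError):
            nd.KnowledgeBase([a, b])

    def test_disjoint_bands_accepted(self):
        a = make_rule(pna_band=(0, 7))
        b = make_rule(pna_band=(8, 365))
        assert len(nd.KnowledgeBase([a, b]).rules) == 2

    @pytest.mark.parametrize(
        "kw", [{"recommended_dose_per_kg": 0}, {"recommended_interval": 5},
               {"ga_band": (40, 30)}, {"tolerance": 1.5}],
    )
    def test_invalid_rule_rejected(self, kw):
        with pytest.raises(KnowledgeBaseError):
            make_rule(**kw)


class TestAssess:
    def test_recommended_dosage_is_correct(self):
        state, rule = make_state(), make_rule()
        a = nd.assess(rule.recommended_dose_mg(state), rule.recommended_interval, state, rule)
        assert a.status == "correct"
        assert a.severity_pct == pytest.approx(100.0)
        assert not a.is_error

    def test_two_and_a_half_fold_dose_is_overdose(self):
        state, rule = make_state(), make_rule()
        a = nd.assess(2.5 * rule.recommended_dose_mg(state), 12, state, rule)
        assert a.status == "overdose"
        assert a.severity_pct == pytest.approx(250.0)

    def test_underdose_below_tolerance(self):
        state, rule = make_state(), make_rule()
        a = nd.assess(0.5 * rule.recommended_dose_mg(state), 12, state, rule)
        assert a.status == "underdose"

    def test_longer_interval_is_prolonged(self):
        state, rule = make_state(), make_rule()
        a = nd.assess(rule.recommended_dose_mg(state), 24, state, rule)
        assert a.status == "prolonged_interval"
        assert a.interval_flag is None

    def test_shorter_interval_is_curtailed(self):
        state, rule = make_state(), make_rule()
        assert nd.assess(rule.recommended_dose_mg(state), 6, state, rule).status == "curtailed_interval"

    def test_combined_defect_counts_once_with_dose_status(self):
        state, rule = make_state(), make_rule()
        a = nd.assess(3 * rule.recommended_dose_mg(state), 24, state, rule)
        assert a.status == "overdose"
        assert a.interval_flag == "prolonged_interval"

    def test_dose_within_tolerance_is_correct(self):
        state, rule = make_state(), make_rule()
        a = nd.assess(1.05 * rule.recommended_dose_mg(state), 12, state, rule)
        assert a.status == "correct"

    def test_nonmatching_rule_is_contract_error(self):
        state = make_state(postnatal_age=30)
        rule = make_rule(pna_band=(0, 7))
        with pytest.raises(ValueError):
            nd.assess(100, 12, state, rule)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        weight=st.floats(600, 4800),
        m1=st.floats(0.2, 3.0),
        m2=st.floats(0.2, 3.0),
    )
    def test_severity_strictly_monotone_in_dose(self, weight, m1, m2):
        state, rule = make_state(weight=weight), make_rule()
        base = rule.recommended_dose_mg(state)
        a1 = nd.assess(m1 * base, 12, state, rule)
        a2 = nd.assess(m2 * base, 12, state, rule)
        if m1 < m2:
            assert a1.severity_pct < a2.severity_pct
        elif m1 > m2:
            assert a1.severity_pct > a2.severity_pct


class TestWarnings:
    def test_warning_for_erroneous_assessment(self):
        state, rule = make_state(), make_rule()
        a = nd.assess(2 * rule.recommended_dose_mg(state), 12, state, rule)
        w = nd.generate_warning(a, "order-entry", "L1")
        assert w.response == "pending"
        assert w.displayed_at == "order-entry"

    def test_correct_assessment_is_contract_error(self):
        state, rule = make_state(), make_rule()
        a = nd.assess(rule.recommended_dose_mg(state), 12, state, rule)
        with pytest.raises(ValueError):
            nd.generate_warning(a, "order-entry")

    def test_renewal_emits_fresh_warning(self):
        state, rule = make_state(), make_rule()
        a = nd.assess(2 * rule.recommended_dose_mg(state), 12, state, rule)
        w1 = nd.generate_warning(a, "order-entry", "L1")
        w2 = nd.generate_warning(a, "order-entry", "L2")
        assert w1 is not w2 and w2.response == "pending"


class TestSeverityCategory:
    @pytest.mark.parametrize(
        "severity, expected",
        [(101, 1), (150, 1), (151, 2), (199, 2), (200, 3), (250, 3), (299, 3)],
    )
    def test_default_bins(self, severity, expected):
        assert severity_category(severity) == expected

    def test_defined_for_overdoses_only(self):
        with pytest.raises(ValueError):
            severity_category(100)

    def test_custom_bins(self):
        assert severity_category(180, bins=(120, 160, 220)) == 3
        assert severity_category(260, bins=(120, 160, 220)) == 4
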