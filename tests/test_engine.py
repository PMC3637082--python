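"""Decision engine: watchdogs, end-of-visit integration, oracle equivalence."""

from datetime import date, datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matcare.engine import (
    evaluate_visit,
    evaluate_watchdogs,
    observation_state,
    record_agreement,
    rule_satisfied,
)
from matcare.errors import DomainError, ValidationError
from matcare.knowledge import condition_codes, resolve_source
from matcare.model import ANCVisit, Observation

from conftest import record_with_observations

PREECLAMPSIA_VISIT = {"blurred_vision": True, "systolic_bp": 150,
                      "diastolic_bp": 95, "proteinuria": True}


class TestWatchdogs:
    def test_low_fhr_fires_exactly_the_fhr_rule(self, ruleset, catalog):
        record, _ = record_with_observations({})
        obs = Observation("fetal_heart_rate", 100, "bpm",
                          datetime(2024, 3, 1, 9, 0))
        alerts = evaluate_watchdogs(record, obs, ruleset, catalog=catalog)
        assert [a.rule_id for a in alerts] == ["fhr_abnormal"]
        assert "120-160" in alerts[0].message
        assert alerts[0].triggering_codes == ("fetal_heart_rate",)

    def test_normal_values_fire_nothing(self, ruleset):
        record, _ = record_with_observations(
            {"systolic_bp": 120, "diastolic_bp": 75, "haemoglobin": 12.0})
        obs = Observation("temperature_c", 37.0, "degC",
                          datetime(2024, 3, 1, 9, 5))
        assert evaluate_watchdogs(record, obs, ruleset) == []

    def test_evaluation_is_deterministic_and_side_effect_free(self, ruleset):
        record, visit = record_with_observations({"systolic_bp": 150})
        obs = Observation("diastolic_bp", 95, "mmHg",
                          datetime(2024, 3, 1, 9, 1))
        before = len(visit.observations)
        first = evaluate_watchdogs(record, obs, ruleset)
        second = evaluate_watchdogs(record, obs, ruleset)
        assert first == second
        assert len(visit.observations) == before

    def test_unknown_code_blocked(self, ruleset):
        record, _ = record_with_observations({})
        with pytest.raises(ValidationError, match="not_a_code"):
            evaluate_watchdogs(record, Observation("not_a_code", 1), ruleset)

    def test_watchdogs_see_history_across_visits(self, ruleset):
        # systolic from an earlier visit combines with a new diastolic entry
        record, _ = record_with_observations({"systolic_bp": 150})
        obs = Observation("diastolic_bp", 80, "mmHg",
                          datetime(2024, 3, 2, 9, 0))
        alerts = evaluate_watchdogs(record, obs, ruleset)
        assert "elevated_bp" in [a.rule_id for a in alerts]


class TestEndOfVisit:
    def test_three_sign_visit_suggests_preeclampsia(self, ruleset, catalog,
                                                    registry):
        record, visit = record_with_observations(PREECLAMPSIA_VISIT)
        findings = evaluate_visit(record, visit, ruleset, catalog=catalog)
        by_id = {f.rule_id: f for f in findings}
        assert "preeclampsia_suspicion" in by_id
        finding = by_id["preeclampsia_suspicion"]
        assert "preeclampsia" in finding.message
        assert any(kind == "referral" for kind, _ in finding.proposed_actions)
        entry, section = resolve_source(
            ruleset.rule(finding.rule_id), registry)
        assert entry.access_level == "open" and section

    @pytest.mark.parametrize("single", [
        {"blurred_vision": True},
        {"proteinuria": True},
        {"systolic_bp": 150, "diastolic_bp": 95},
    ])
    def test_single_sign_does_not_suggest_preeclampsia(self, ruleset, single):
        record, visit = record_with_observations(single)
        findings = evaluate_visit(record, visit, ruleset)
        assert "preeclampsia_suspicion" not in [f.rule_id for f in findings]

    def test_empty_history_yields_no_findings(self, ruleset):
        record, visit = record_with_observations({})
        assert evaluate_visit(record, visit, ruleset) == []

    def test_integration_unions_prior_visits(self, ruleset):
        # elevated BP recorded at visit 1, proteinuria only at visit 2
        record, _ = record_with_observations(
            {"systolic_bp": 150, "diastolic_bp": 95})
        visit2 = ANCVisit(visit_number=2, date=date(2024, 4, 1))
        visit2.observations.append(Observation(
            "proteinuria", True, "", datetime(2024, 4, 1, 9, 0)))
        record.open_pregnancy().visits.append(visit2)
        findings = evaluate_visit(record, visit2, ruleset)
        assert "preeclampsia_suspicion" in [f.rule_id for f in findings]

    def test_latest_value_wins_within_history(self, ruleset):
        record, visit = record_with_observations({"systolic_bp": 150})
        visit.observations.append(Observation(
            "systolic_bp", 118, "mmHg", datetime(2024, 3, 1, 10, 0)))
        visit.observations.append(Observation(
            "proteinuria", True, "", datetime(2024, 3, 1, 10, 1)))
        findings = evaluate_visit(record, visit, ruleset)
        assert "preeclampsia_suspicion" not in [f.rule_id for f in findings]


class TestAgreement:
    def test_agreement_recorded_with_user_and_time(self, ruleset):
        record, visit = record_with_observations(PREECLAMPSIA_VISIT)
        visit.findings = evaluate_visit(record, visit, ruleset)
        audit_before = len(record.audit_log)
        f = record_agreement(record, visit, "preeclampsia_suspicion",
                             "disagree", "nurse1",
                             now=datetime(2024, 3, 1, 11, 0))
        assert f.agreement == "disagree" and f.agreed_by == "nurse1"
        assert len(record.audit_log) == audit_before + 1

    def test_disagreement_never_blocks(self, ruleset):
        record, visit = record_with_observations(PREECLAMPSIA_VISIT)
        visit.findings = evaluate_visit(record, visit, ruleset)
        visit.finalization_pending = True
        for f in visit.findings:
            record_agreement(record, visit, f.rule_id, "disagree", "n1")
        assert visit.finalized  # disagree completes finalization too

    def test_unknown_finding_rejected(self, ruleset):
        record, visit = record_with_observations({})
        with pytest.raises(DomainError):
            record_agreement(record, visit, "nope", "agree", "n1")


# ------------------------------------------------------- oracle equivalence

def random_states(ruleset, n, seed):
    """Randomized record states over the vocabulary (values or missing)."""
    rng = np.random.default_rng(seed)
    codes = sorted(ruleset.vocabulary)
    states = []
    for _ in range(n):
        state = {}
        for code in codes:
            r = rng.random()
            if r < 0.35:
                continue  # missing
            entry = ruleset.vocabulary[code]
            if entry.kind == "boolean":
                state[code] = bool(rng.random() < 0.5)
            else:
                state[code] = float(np.round(rng.uniform(0, 200), 1))
        states.append(state)
    return states


def test_production_evaluator_matches_brute_force_oracle(ruleset):
    from matcare.oracles import condition_oracle
    for state in random_states(ruleset, 2000, seed=42):
        for rule in ruleset.rules:
            assert rule_satisfied(rule, state) == \
                condition_oracle(state, rule.condition), (rule.rule_id, state)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(perm_seed=st.integers(0, 10_000))
def test_order_independence_of_entry_order(ruleset, perm_seed):
    """Permuting observation entry order leaves evaluation unchanged."""
    rng = np.random.default_rng(perm_seed)
    values = {"systolic_bp": 150, "diastolic_bp": 95, "proteinuria": True,
              "haemoglobin": 9.5, "temperature_c": 38.5}
    codes = list(values)
    rng.shuffle(codes)
    record, visit = record_with_observations(
        {c: values[c] for c in codes})
    findings = [f.rule_id for f in evaluate_visit(record, visit, ruleset)]
    assert findings == sorted(findings)
    assert set(findings) == {"anaemia", "preeclampsia_suspicion"}


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_presence_rules_are_monotone_under_new_observations(ruleset, seed):
    """Adding an observation never un-fires a presence/exceedance rule.

    Checked on the shipped rules whose predicates are all 'present' or
    upward threshold tests (here: the vaginal-bleeding danger sign).
    """
    rule = ruleset.rule("vaginal_bleeding_danger")
    state = dict(random_states(ruleset, 1, seed)[0])
    state["vaginal_bleeding"] = True
    assert rule_satisfied(rule, state)
    state["fundal_height_cm"] = 30.0
    state["oedema"] = True
    assert rule_satisfied(rule, state)


def test_observation_state_uses_timestamps_not_entry_order():
    early = Observation("systolic_bp", 150, "mmHg", datetime(2024, 3, 1, 9))
    late = Observation("systolic_bp", 120, "mmHg", datetime(2024, 3, 1, 10))
    assert observation_state([late, early])["systolic_bp"] == 120
    assert observation_state([early, late])["systolic_bp"] == 120
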