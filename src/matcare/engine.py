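"""Rule evaluation: instant watchdogs and end-of-visit integrated findings.

Both tiers evaluate against the *whole* record state of the open
pregnancy — the union of all observations from this and prior visits,
reduced to the latest value per code — so an algorithm can integrate, say,
a history item from the first visit with a lab result from the third.
Watchdogs differ only in their trigger moment (each new entry), not in
the data they see.

Missing data makes a predicate unsatisfied (three-valued logic collapsed
to false): the checklist workflow separately guarantees that critical
items are addressed or carry a documented deviation reason.

Evaluation is side-effect-free and deterministic; findings are always
recomputed, never cached, so correcting data and re-finalizing a visit
yields fresh results.  The engine never enforces anything: providers
record agreement or disagreement, and disagreement never blocks care.
"""

from __future__ import annotations

from datetime import datetime
from typing import Callable, Iterable, Optional

from .errors import DomainError, ValidationError
from .knowledge import (
    Combinator,
    Predicate,
    Rule,
    RuleSet,
    TranslationCatalog,
    condition_codes,
)
from .model import Alert, ANCVisit, Finding, Observation, PatientRecord
from .records import audit

_NUM_OPS: dict = {
    "lt": lambda v, t: v < t,
    "le": lambda v, t: v <= t,
    "gt": lambda v, t: v > t,
    "ge": lambda v, t: v >= t,
}


def compile_condition(node) -> Callable[[dict], bool]:
    """Compile a condition tree into a closure over the state map."""
    if isinstance(node, Combinator):
        children = tuple(compile_condition(c) for c in node.children)
        if node.op == "all":
            return lambda s: all(c(s) for c in children)
        if node.op == "any":
            return lambda s: any(c(s) for c in children)
        child = children[0]
        return lambda s: not child(s)
    assert isinstance(node, Predicate)
    code, op, threshold = node.code, node.op, node.value
    if op == "present":
        return lambda s: s.get(code) not in (None, False)
    if op == "absent":
        return lambda s: s.get(code) in (None, False)
    if op in _NUM_OPS:
        cmp = _NUM_OPS[op]

        def numeric(s, code=code, threshold=threshold, cmp=cmp):
            v = s.get(code)
            if v is None or isinstance(v, bool) \
                    or not isinstance(v, (int, float)):
                return False
            return cmp(v, threshold)

        return numeric
    if op == "eq":
        return lambda s: s.get(code) is not None and s.get(code) == threshold
    if op == "ne":
        return lambda s: s.get(code) is not None and s.get(code) != threshold
    raise ValidationError(f"unknown comparator {op!r}")


_compiled_cache: dict = {}


def _compiled(rule: Rule) -> Callable[[dict], bool]:
    fn = _compiled_cache.get(rule)
    if fn is None:
        fn = _compiled_cache[rule] = compile_condition(rule.condition)
    return fn


def observation_state(observations: Iterable[Observation]) -> dict:
    """Reduce an observation stream to the latest value per code.

    'Latest' follows ``observed_at`` where present (entry order breaks
    ties), so the map is invariant under permutation of entry order.
    """
    stamped = []
    for i, obs in enumerate(observations):
        stamped.append((obs.observed_at or datetime.min, i, obs))
    stamped.sort(key=lambda x: (x[0], x[1]))
    return {obs.code: obs.value for _, _, obs in stamped}


def record_state(record: PatientRecord,
                 up_to_visit: Optional[ANCVisit] = None) -> dict:
    """State of the open pregnancy across all visits (optionally up to and
    including a given visit)."""
    preg = record.open_pregnancy()
    if preg is None and record.pregnancies:
        preg = record.pregnancies[-1]
    obs: list = []
    if preg is not None:
        for visit in preg.visits:
            obs.extend(visit.observations)
            if up_to_visit is not None \
                    and visit.visit_number == up_to_visit.visit_number:
                break
    return observation_state(obs)


def rule_satisfied(rule: Rule, state: dict) -> bool:
    return _compiled(rule)(state)


def _localize(catalog: Optional[TranslationCatalog], key: str,
              language: Optional[str]) -> str:
    if catalog is None:
        return key
    return catalog.translate(key, language)


def evaluate_watchdogs(record: PatientRecord, new_observation: Observation,
                       ruleset: RuleSet, *,
                       catalog: Optional[TranslationCatalog] = None,
                       language: Optional[str] = None,
                       now: Optional[datetime] = None) -> list:
    """Instant alerts triggered by one newly-entered observation.

    Returns exactly the ``instant_watchdog`` rules that reference the new
    observation's code and are satisfied by the record state including
    the new observation — so an alert re-fires on each new *triggering*
    entry, but entering an unrelated value never repeats old alerts.
    Pure function: nothing is stored.
    """
    if new_observation.code not in ruleset.vocabulary:
        raise ValidationError(
            f"observation code {new_observation.code!r} not in vocabulary")
    state = record_state(record)
    state[new_observation.code] = new_observation.value
    fired_at = now or new_observation.observed_at or datetime.now()
    alerts = []
    for rule in ruleset.watchdogs():
        if new_observation.code in condition_codes(rule.condition) \
                and rule_satisfied(rule, state):
            present = tuple(sorted(
                c for c in condition_codes(rule.condition) if c in state))
            alerts.append(Alert(
                rule_id=rule.rule_id, fired_at=fired_at,
                triggering_codes=present,
                message=_localize(catalog, rule.message_key, language)))
    return alerts


def evaluate_visit(record: PatientRecord, visit: ANCVisit, ruleset: RuleSet,
                   *, catalog: Optional[TranslationCatalog] = None,
                   language: Optional[str] = None,
                   now: Optional[datetime] = None) -> list:
    """End-of-visit findings over this visit's and all prior observations."""
    state = record_state(record, up_to_visit=visit)
    evaluated_at = now or datetime.now()
    findings = []
    for rule in ruleset.end_of_visit_rules():
        if rule_satisfied(rule, state):
            findings.append(Finding(
                rule_id=rule.rule_id,
                message=_localize(catalog, rule.message_key, language),
                proposed_actions=tuple(
                    (a.kind, _localize(catalog, a.description_key, language))
                    for a in rule.actions),
                source_document_id=rule.source.document_id,
                source_section=rule.source.section_label,
                evaluated_at=evaluated_at))
    return findings


def record_agreement(record: PatientRecord, visit: ANCVisit, rule_id: str,
                     stance: str, user: str,
                     now: Optional[datetime] = None) -> Finding:
    """Store the provider's stance on one finding; never blocks on disagree.

    When every finding of a pending visit has a stance, the visit flips to
    finalized.
    """
    if stance not in ("agree", "disagree"):
        raise DomainError(f"stance must be agree|disagree, got {stance!r}")
    target = None
    for f in visit.findings:
        if f.rule_id == rule_id:
            target = f
            break
    if target is None:
        raise DomainError(f"no finding {rule_id!r} in visit "
                          f"{visit.visit_number}")
    target.agreement = stance
    target.agreed_by = user
    target.agreed_at = now or datetime.now()
    audit(record, user, f"{stance} on finding {rule_id} "
                        f"(visit {visit.visit_number})", now)
    if visit.finalization_pending and all(
            f.agreement != "unset" for f in visit.findings):
        visit.finalized = True
        visit.finalization_pending = False
    return target
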