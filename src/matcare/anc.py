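"""Checklist-guided antenatal visit workflow, scheduling and overdue search.

The checklist walks the provider step by step through history-taking,
examination, laboratory, counselling and preventive measures.  Items move
``pending -> done`` (with results) or ``pending -> not_done`` (with a
documented deviation reason: patient refusal, missing equipment, or
'other' with a mandatory note).  Completing an observation-producing item
pushes coded observations into the record and triggers the instant
watchdogs, so decision support arrives at the point of care rather than
at the end of the visit.

Finalization requires every critical item to be addressed (done, or
not-done with a reason), runs the end-of-visit integration rules, and
holds the visit in a pending state until the provider has recorded
agreement or disagreement with each finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Optional

import yaml

from .engine import evaluate_visit, evaluate_watchdogs
from .errors import (
    DomainError,
    ItemStateError,
    PendingCriticalItems,
    ValidationError,
    VisitOrderError,
)
from .knowledge import RuleSet, TranslationCatalog
from .model import (
    DEVIATION_CATEGORIES,
    ANCVisit,
    DeviationReason,
    ItemState,
    Observation,
    PatientRecord,
)
from .records import audit, gestational_age

SECTIONS = ("history", "examination", "laboratory", "counselling",
            "preventive_measures")


@dataclass(frozen=True)
class ChecklistItem:
    item_id: str
    section: str
    label: str
    codes: tuple = ()  # observation codes produced when done
    action: str = ""  # pure-action kind when no codes
    critical: bool = False


@dataclass
class ChecklistTemplate:
    version: str
    items: tuple  # of ChecklistItem, in guided order

    def item(self, item_id: str) -> ChecklistItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def critical_ids(self) -> tuple:
        return tuple(i.item_id for i in self.items if i.critical)


def load_template(path, *, vocabulary: Optional[dict] = None) -> ChecklistTemplate:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    items = []
    seen = set()
    for section in data.get("sections", []):
        name = section.get("name")
        if name not in SECTIONS:
            raise ValidationError(f"unknown checklist section {name!r}")
        for raw in section.get("items", []):
            iid = raw["id"]
            if iid in seen:
                raise ValidationError(f"duplicate checklist item id {iid!r}")
            seen.add(iid)
            codes = tuple(raw.get("codes", []))
            if vocabulary is not None:
                for code in codes:
                    if code not in vocabulary:
                        raise ValidationError(
                            f"checklist item {iid!r} uses code {code!r} "
                            "not in vocabulary")
            items.append(ChecklistItem(
                item_id=iid, section=name, label=raw.get("label", iid),
                codes=codes, action=raw.get("action", ""),
                critical=bool(raw.get("critical", False))))
    return ChecklistTemplate(version=str(data.get("template_version", "")),
                             items=tuple(items))


# ------------------------------------------------------------------ schedule

@dataclass(frozen=True)
class ScheduleWindow:
    visit_number: int
    start_week: int
    end_week: int

    def dates(self, lmp: date) -> tuple:
        """Calendar window [start, end] mapped from gestational weeks."""
        return (lmp + timedelta(weeks=self.start_week),
                lmp + timedelta(weeks=self.end_week, days=6))


@dataclass(frozen=True)
class VisitSchedule:
    windows: tuple  # of ScheduleWindow, ordered by visit number


def load_schedule(path) -> VisitSchedule:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    windows = []
    for raw in data.get("visits", []):
        windows.append(ScheduleWindow(int(raw["visit"]),
                                      int(raw["start_week"]),
                                      int(raw["end_week"])))
    windows.sort(key=lambda w: w.visit_number)
    for w in windows:
        if w.end_week < w.start_week:
            raise ValidationError(
                f"schedule visit {w.visit_number}: window end before start")
    return VisitSchedule(tuple(windows))


# ------------------------------------------------------------------- visits

def start_visit(record: PatientRecord, visit_date: date,
                template: ChecklistTemplate, *, user: str = "system",
                now: Optional[datetime] = None) -> ANCVisit:
    """Open a new checklist visit with every item pending."""
    preg = record.open_pregnancy()
    if preg is None:
        raise DomainError(
            f"patient {record.patient_id!r} has no open pregnancy")
    if visit_date < preg.lmp:
        raise VisitOrderError(f"visit date {visit_date} precedes LMP {preg.lmp}")
    if preg.visits and visit_date <= preg.visits[-1].date:
        raise VisitOrderError(
            f"visit date {visit_date} not after previous visit "
            f"{preg.visits[-1].date}")
    visit = ANCVisit(visit_number=len(preg.visits) + 1, date=visit_date,
                     item_states={i.item_id: ItemState()
                                  for i in template.items})
    preg.visits.append(visit)
    audit(record, user, f"start visit {visit.visit_number} on {visit_date}",
          now)
    return visit


def _default_obs_time(visit: ANCVisit) -> datetime:
    # deterministic in-visit ordering: 09:00 plus one minute per event
    n = len(visit.observations)
    return datetime.combine(visit.date, time(9, 0)) + timedelta(minutes=n)


def complete_item(record: PatientRecord, visit: ANCVisit, item_id: str,
                  template: ChecklistTemplate, *, result=None,
                  deviation: Optional[DeviationReason] = None,
                  ruleset: Optional[RuleSet] = None,
                  catalog: Optional[TranslationCatalog] = None,
                  language: Optional[str] = None,
                  user: str = "system",
                  now: Optional[datetime] = None) -> list:
    """Mark one pending item done (with results) or not-done (with reason).

    Returns the instant watchdog alerts raised by any newly-entered
    observation; the alerts are also appended to the visit.
    """
    if visit.finalized:
        raise ItemStateError("visit already finalized")
    item = template.item(item_id)
    state = visit.item_states.get(item_id)
    if state is None:
        state = visit.item_states[item_id] = ItemState()
    if state.status != "pending":
        raise ItemStateError(f"item {item_id!r} already {state.status}")

    when = now or _default_obs_time(visit)
    alerts: list = []
    if deviation is not None:
        if deviation.category not in DEVIATION_CATEGORIES:
            raise ValidationError(
                f"unknown deviation category {deviation.category!r}")
        if deviation.category == "other" and not deviation.note.strip():
            raise ValidationError(
                "deviation category 'other' requires a free-text note")
        state.status = "not_done"
        state.deviation = deviation
    else:
        if item.codes:
            if not isinstance(result, dict):
                if len(item.codes) != 1:
                    raise ValidationError(
                        f"item {item_id!r} needs a result for each of "
                        f"{item.codes}")
                result = {item.codes[0]: result}
            missing = [c for c in item.codes if c not in result]
            if missing:
                raise ValidationError(
                    f"item {item_id!r} missing results for {missing}")
            for offset, code in enumerate(item.codes):
                unit = ""
                if ruleset is not None and code in ruleset.vocabulary:
                    unit = ruleset.vocabulary[code].unit
                obs = Observation(code=code, value=result[code], unit=unit,
                                  observed_at=when + timedelta(seconds=offset))
                if ruleset is not None:
                    alerts.extend(evaluate_watchdogs(
                        record, obs, ruleset, catalog=catalog,
                        language=language, now=obs.observed_at))
                visit.observations.append(obs)
        state.status = "done"
        state.results = dict(result) if isinstance(result, dict) else None
    state.completed_at = when
    state.user = user
    # de-duplicate alerts raised within one multi-code item; alerts DO
    # re-fire on later triggering observations elsewhere in the visit
    fresh = []
    for a in alerts:
        if a.rule_id not in {f.rule_id for f in fresh}:
            fresh.append(a)
    visit.alerts.extend(fresh)
    audit(record, user, f"item {item_id} -> {state.status} "
                        f"(visit {visit.visit_number})", when)
    return fresh


@dataclass
class VisitSummary:
    """Plain-text exportable end-of-visit summary."""

    visit_number: int
    date: date
    done: tuple
    not_done: tuple  # of (item_id, category, note)
    pending: tuple
    findings: list

    def to_text(self) -> str:
        lines = [f"Visit {self.visit_number} summary ({self.date})"]
        lines.append(f"  done ({len(self.done)}): " + ", ".join(self.done))
        for item_id, category, note in self.not_done:
            reason = category + (f": {note}" if note else "")
            lines.append(f"  not done: {item_id} [{reason}]")
        if self.pending:
            lines.append("  pending: " + ", ".join(self.pending))
        if self.findings:
            lines.append(f"  findings ({len(self.findings)}):")
            for f in self.findings:
                lines.append(f"    - {f.rule_id}: {f.message}")
                for kind, desc in f.proposed_actions:
                    lines.append(f"        [{kind}] {desc}")
                lines.append(f"        source: {f.source_document_id} "
                             f"({f.source_section})")
        else:
            lines.append("  findings: none")
        return "\n".join(lines)


def finalize_visit(record: PatientRecord, visit: ANCVisit, ruleset: RuleSet,
                   template: ChecklistTemplate, *,
                   catalog: Optional[TranslationCatalog] = None,
                   language: Optional[str] = None, user: str = "system",
                   now: Optional[datetime] = None) -> VisitSummary:
    """Run the end-of-visit integration and produce the summary page.

    Fails while critical items are still pending.  The visit is marked
    finalized immediately when there are no findings; otherwise it stays
    pending until every finding has an agreement stance recorded.
    """
    pending_critical = [iid for iid in template.critical_ids()
                        if visit.item_states.get(iid, ItemState()).status
                        == "pending"]
    if pending_critical:
        raise PendingCriticalItems(pending_critical)
    findings = evaluate_visit(record, visit, ruleset, catalog=catalog,
                              language=language, now=now)
    visit.findings = findings
    if findings:
        visit.finalization_pending = True
        visit.finalized = False
    else:
        visit.finalized = True
        visit.finalization_pending = False
    done, not_done, still_pending = [], [], []
    for iid, st in sorted(visit.item_states.items()):
        if st.status == "done":
            done.append(iid)
        elif st.status == "not_done":
            dev = st.deviation or DeviationReason("other", "")
            not_done.append((iid, dev.category, dev.note))
        else:
            still_pending.append(iid)
    audit(record, user, f"finalize visit {visit.visit_number} "
                        f"({len(findings)} findings)", now)
    return VisitSummary(visit_number=visit.visit_number, date=visit.date,
                        done=tuple(done), not_done=tuple(not_done),
                        pending=tuple(still_pending), findings=findings)


# ------------------------------------------------------------------ overdue

def next_scheduled_visit(record: PatientRecord, schedule: VisitSchedule):
    """First schedule window not yet covered by a completed visit.

    Returns ``(window, (start_date, end_date))`` or ``None`` when the
    schedule is exhausted or no pregnancy is open.
    """
    preg = record.open_pregnancy()
    if preg is None:
        return None
    n_visits = len(preg.visits)
    for window in schedule.windows:
        if window.visit_number > n_visits:
            return window, window.dates(preg.lmp)
    return None


def find_overdue(store, today: date, schedule: VisitSchedule) -> list:
    """Women with an open pregnancy whose next visit window has passed.

    Returns ``[(patient_id, window, window_end_date), ...]`` sorted by id.
    Delivered pregnancies are excluded — their follow-up belongs to the
    postpartum pathway.
    """
    out = []
    for record in store:
        nxt = next_scheduled_visit(record, schedule)
        if nxt is None:
            continue
        window, (_, end) = nxt
        if end < today:
            out.append((record.patient_id, window, end))
    return sorted(out, key=lambda x: x[0])


def gestational_age_today(record: PatientRecord, today: date):
    preg = record.open_pregnancy()
    if preg is None:
        return None
    return gestational_age(preg.lmp, today)
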