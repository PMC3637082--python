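"""Record-level operations: creation, gestational-age arithmetic, validation.

The expected delivery date is derived as LMP + 280 days, the standard
obstetric rule.  Validation distinguishes hard invariant violations
(errors) from clinically-plausible-but-unusual values (warnings, e.g. age
outside 10-60 years or a delivery more than six weeks from the EDD).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import NamedTuple, Optional

from .errors import ValidationError
from .model import (
    GESTATION_DAYS,
    AuditEntry,
    PatientRecord,
    Pregnancy,
)


class GestationalAge(NamedTuple):
    weeks: int
    days: int

    @property
    def total_days(self) -> int:
        return self.weeks * 7 + self.days

    def __str__(self) -> str:  # e.g. "32+4"
        return f"{self.weeks}+{self.days}"


@dataclass
class Issue:
    """One validation finding: the offending field and the broken invariant."""

    field: str
    message: str
    severity: str = "error"  # error | warning


def expected_delivery_date(lmp: date) -> date:
    return lmp + timedelta(days=GESTATION_DAYS)


def gestational_age(lmp: date, on: date) -> GestationalAge:
    """Completed weeks plus remainder days between LMP and ``on``."""
    if on < lmp:
        raise ValidationError(f"date {on} precedes LMP {lmp}")
    total = (on - lmp).days
    return GestationalAge(total // 7, total % 7)


def audit(record: PatientRecord, user: str, action: str,
          now: Optional[datetime] = None) -> None:
    """Append one audit entry; every mutating operation calls this exactly once."""
    record.audit_log.append(AuditEntry(now or datetime.now(), user, action))


def new_record(patient_id: str, name: str, age: int, gravidity: int,
               parity: int, lmp: date, *, user: str = "system",
               now: Optional[datetime] = None,
               today: Optional[date] = None) -> PatientRecord:
    """Create a record with one open pregnancy and a computed EDD.

    ``today`` anchors the LMP-in-the-past check (defaults to the wall
    clock); pass it explicitly for reproducible cohort generation.
    """
    today = today or date.today()
    if lmp > today:
        raise ValidationError(f"LMP {lmp} lies in the future (today {today})")
    record = PatientRecord(patient_id=patient_id, name=name, age=age,
                           gravidity=gravidity, parity=parity)
    record.pregnancies.append(
        Pregnancy(lmp=lmp, edd=expected_delivery_date(lmp)))
    issues = validate_record(record, today=today)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise ValidationError("invalid new record", errors)
    audit(record, user, f"register patient {patient_id}", now)
    return record


def validate_record(record: PatientRecord, *, today: Optional[date] = None,
                    include_warnings: bool = False) -> list:
    """Check every structural invariant; an empty (error) list means valid."""
    today = today or date.today()
    issues: list = []

    if not record.patient_id:
        issues.append(Issue("patient_id", "must be a non-empty string"))
    if record.parity > record.gravidity:
        issues.append(Issue(
            "parity", f"parity {record.parity} exceeds gravidity "
                      f"{record.gravidity}"))
    if not 10 <= record.age <= 60:
        issues.append(Issue("age", f"age {record.age} outside 10-60 years",
                            severity="warning"))

    open_count = sum(1 for p in record.pregnancies if p.open)
    if open_count > 1:
        issues.append(Issue("pregnancies",
                            f"{open_count} pregnancies open simultaneously"))

    save_time = datetime.combine(today, datetime.max.time())
    for pi, preg in enumerate(record.pregnancies):
        loc = f"pregnancies[{pi}]"
        if preg.edd != expected_delivery_date(preg.lmp):
            issues.append(Issue(f"{loc}.edd",
                                f"edd {preg.edd} != lmp + {GESTATION_DAYS} days"))
        prev: Optional[date] = None
        for vi, visit in enumerate(preg.visits):
            vloc = f"{loc}.visits[{vi}]"
            if visit.date < preg.lmp:
                issues.append(Issue(f"{vloc}.date",
                                    f"visit date {visit.date} precedes LMP"))
            if prev is not None and visit.date <= prev:
                issues.append(Issue(f"{vloc}.date",
                                    "visit dates must strictly increase"))
            prev = visit.date
            for oi, obs in enumerate(visit.observations):
                if obs.observed_at is not None and obs.observed_at > save_time:
                    issues.append(Issue(
                        f"{vloc}.observations[{oi}].observed_at",
                        f"timestamp {obs.observed_at} lies in the future"))
                if isinstance(obs.value, (int, float)) \
                        and not isinstance(obs.value, bool) and not obs.unit:
                    issues.append(Issue(
                        f"{vloc}.observations[{oi}].unit",
                        f"numeric observation {obs.code!r} lacks a unit"))
        if preg.delivery is not None:
            window = timedelta(weeks=6)
            dd = preg.delivery.delivery_time.date()
            if not (preg.edd - window <= dd <= preg.edd + window):
                issues.append(Issue(
                    f"{loc}.delivery.delivery_time",
                    f"delivery {dd} more than 6 weeks from EDD {preg.edd}",
                    severity="warning"))
        if preg.labor is not None:
            last_t = None
            last_d = None
            for mi, m in enumerate(preg.labor.measurements):
                mloc = f"{loc}.labor.measurements[{mi}]"
                if last_t is not None and m.t <= last_t:
                    issues.append(Issue(f"{mloc}.t",
                                        "times must strictly increase"))
                if last_d is not None and m.dilatation < last_d:
                    issues.append(Issue(f"{mloc}.dilatation",
                                        "dilatation must be non-decreasing"))
                if not 0 <= m.dilatation <= 10:
                    issues.append(Issue(f"{mloc}.dilatation",
                                        f"{m.dilatation} outside [0, 10] cm"))
                last_t, last_d = m.t, m.dilatation

    if include_warnings:
        return issues
    return [i for i in issues if i.severity == "error"]
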