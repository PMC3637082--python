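"""Seeded synthetic cohorts: ANC records, danger-sign injection, labor traces.

The generator exists so every other module is testable without any real
patient data.  It drives the *real* workflow API (register, start visit,
complete checklist items, finalize, agree), so generated records carry
full item states, observations, watchdog alerts, findings and audit
trails, and always pass validation and the XML round trip.

Danger signs are injected as the complete observation pattern the
corresponding shipped rule needs (e.g. preeclampsia: elevated blood
pressure AND proteinuria AND blurred vision), so a configured prevalence
maps one-to-one onto the expected finding rate.  All randomness flows
from one explicitly-seeded generator; the same spec yields identical
cohorts, byte for byte.

The generator targets engine coverage, not demography: risk factors are
independent, there is no seasonality, and attendance is a plain Bernoulli
draw per scheduled window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional

import numpy as np

from . import anc, partograph
from .defaults import (
    default_catalog,
    default_ruleset,
    default_schedule,
    default_template,
)
from .engine import record_agreement
from .errors import ValidationError
from .model import DeliveryRecord, DeviationReason, LaborSession, Measurement
from .records import new_record
from .xmlio import RecordStore

LABOR_PATTERNS = ("normal", "slow", "obstructed")

#: full observation pattern per injectable rule (code -> value or sampler)
_INJECTIONS = {
    "preeclampsia_suspicion": lambda rng: {
        "systolic_bp": int(rng.integers(142, 165)),
        "diastolic_bp": int(rng.integers(92, 108)),
        "proteinuria": True,
        "blurred_vision": True,
    },
    "anaemia": lambda rng: {
        "haemoglobin": round(float(rng.uniform(7.5, 10.5)), 1),
    },
    "severe_anaemia": lambda rng: {
        "haemoglobin": round(float(rng.uniform(5.0, 6.8)), 1),
    },
    "fever": lambda rng: {
        "temperature_c": round(float(rng.uniform(38.1, 39.8)), 1),
    },
    "vaginal_bleeding_danger": lambda rng: {"vaginal_bleeding": True},
    "fhr_abnormal": lambda rng: {
        "fetal_heart_rate": int(rng.choice(
            list(range(90, 118)) + list(range(163, 185)))),
    },
    "severe_hypertension": lambda rng: {
        "systolic_bp": int(rng.integers(162, 185)),
        "diastolic_bp": int(rng.integers(112, 125)),
    },
}

_NAMES = ("Abena", "Adjoa", "Akosua", "Ama", "Awa", "Efua", "Esi",
          "Fatima", "Halima", "Mariam", "Neema", "Rahma", "Salma", "Yaa",
          "Zainab")


@dataclass
class SyntheticSpec:
    """Cohort-generation parameters.

    prevalence maps rule id -> probability that a woman's record carries
    the full observation pattern for that rule; labor_pattern_mix gives
    the probabilities of normal / slow / obstructed progress among
    delivered women; attendance is the probability that a scheduled visit
    window is actually attended.
    """

    n_patients: int = 100
    seed: int = 0
    prevalence: dict = field(default_factory=lambda: {
        "preeclampsia_suspicion": 0.05,
        "anaemia": 0.15,
        "fever": 0.04,
        "vaginal_bleeding_danger": 0.02,
        "fhr_abnormal": 0.04,
    })
    labor_pattern_mix: dict = field(default_factory=lambda: {
        "normal": 0.7, "slow": 0.2, "obstructed": 0.1})
    attendance: float = 0.85
    #: reference 'today' anchoring gestational ages; fixed for determinism
    as_of: date = date(2024, 7, 1)

    def validate(self) -> None:
        for rid, p in self.prevalence.items():
            if rid not in _INJECTIONS:
                raise ValidationError(f"no injection pattern for rule {rid!r}")
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"prevalence[{rid!r}]={p} outside [0,1]")
        if not 0.0 <= self.attendance <= 1.0:
            raise ValidationError("attendance outside [0,1]")
        total = sum(self.labor_pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"labor pattern mix sums to {total}, expected 1")
        for name in self.labor_pattern_mix:
            if name not in LABOR_PATTERNS:
                raise ValidationError(f"unknown labor pattern {name!r}")


# ------------------------------------------------------------ labor traces

def _ceil_half(x: float) -> float:
    return math.ceil(x * 2.0) / 2.0


def _floor_half(x: float) -> float:
    return math.floor(x * 2.0) / 2.0


def generate_labor_trace(pattern: str, seed: int,
                         config: partograph.PartographConfig
                         = partograph.DEFAULT_CONFIG, *,
                         onset: Optional[datetime] = None) -> LaborSession:
    """One labor trace with a guaranteed zone profile.

    ``normal`` traces never fall below the alert line; ``slow`` traces
    enter the alert zone but never the action zone; ``obstructed`` traces
    stall and cross the action line.  Measurements are hourly, dilatation
    in half-centimetre steps, fetal heart rate inside the normal band.
    """
    if pattern not in LABOR_PATTERNS:
        raise ValidationError(
            f"unknown labor pattern {pattern!r}; expected one of "
            f"{LABOR_PATTERNS}")
    rng = np.random.default_rng(seed)
    cfg = config
    d0, s, full = cfg.onset_dilatation, cfg.line_slope, cfg.full_dilatation
    session = LaborSession(active_phase_onset=onset
                           or datetime(2024, 1, 1, 6, 0))

    def fhr() -> float:
        return float(rng.integers(int(cfg.fhr_low), int(cfg.fhr_high) + 1))

    points: list = []
    if pattern == "normal":
        rate = float(rng.uniform(1.05, 1.8)) * s
        t = 0.0
        while True:
            d = min(full, _ceil_half(d0 + rate * t))
            d = max(d, partograph.alert_line(cfg, t))  # stay at/above line
            points.append((t, d))
            if d >= full:
                break
            t += 1.0
    elif pattern == "slow":
        rate = float(rng.uniform(0.4, 0.7)) * s
        t_switch = float(rng.integers(3, 6))
        t, d = 0.0, d0
        while d < full:
            if t == 0.0:
                d = d0
            elif t <= t_switch:
                d = max(d, _floor_half(d0 + rate * t))
            else:
                d = min(full, _ceil_half(d + 2.0 * s))
            ac = partograph.action_line(cfg, t)
            if ac is not None and d <= ac:
                d = min(full, ac + 0.5)  # keep strictly above the action line
            points.append((t, d))
            if d >= full:
                break
            t += 1.0
    else:  # obstructed
        rate = float(rng.uniform(0.8, 1.2)) * s
        t_stall = float(rng.integers(2, 4))
        t = 0.0
        crossed = False
        while not crossed:
            if t <= t_stall:
                d = min(full - 1.0, _floor_half(d0 + rate * t))
                d = max(d, d0)
            # after t_stall: d frozen at its last value
            points.append((t, d))
            ac = partograph.action_line(cfg, t)
            crossed = ac is not None and d <= ac
            t += 1.0

    last_d = None
    for t, d in points:
        if last_d is not None:
            d = max(d, last_d)
        last_d = d
        session.measurements.append(Measurement(t=t, dilatation=d, fhr=fhr()))
    return session


# ----------------------------------------------------------------- cohorts

def _normal_results(rng, item: anc.ChecklistItem, weeks: int) -> dict:
    out = {}
    for code in item.codes:
        if code == "systolic_bp":
            out[code] = int(rng.integers(95, 136))
        elif code == "diastolic_bp":
            out[code] = int(rng.integers(58, 86))
        elif code == "temperature_c":
            out[code] = round(float(rng.uniform(36.2, 37.4)), 1)
        elif code == "fetal_heart_rate":
            out[code] = int(rng.integers(120, 161))
        elif code == "haemoglobin":
            out[code] = round(float(rng.uniform(11.1, 14.5)), 1)
        elif code == "weight_kg":
            out[code] = round(float(rng.uniform(48, 90)), 1)
        elif code == "fundal_height_cm":
            out[code] = float(max(10, weeks + int(rng.integers(-2, 3))))
        else:  # boolean danger signs default to absent
            out[code] = False
    return out


def generate_patient(spec: SyntheticSpec, index: int, rng,
                     *, ruleset=None, template=None, schedule=None,
                     catalog=None):
    """One synthetic record driven through the real workflow API."""
    ruleset = ruleset or default_ruleset()
    template = template or default_template()
    schedule = schedule or default_schedule()
    catalog = catalog or default_catalog()
    user = "synth"

    ga_days = int(rng.integers(13 * 7, 44 * 7))
    lmp = spec.as_of - timedelta(days=ga_days)
    gravidity = int(rng.integers(1, 7))
    parity = int(rng.integers(0, gravidity))
    record = new_record(
        patient_id=f"SYN-{index:05d}",
        name=str(rng.choice(_NAMES)), age=int(rng.integers(16, 46)),
        gravidity=gravidity, parity=parity, lmp=lmp, user=user,
        now=datetime.combine(lmp + timedelta(weeks=8), time(8, 0)),
        today=spec.as_of)
    preg = record.open_pregnancy()

    injections = {rid: _INJECTIONS[rid](rng)
                  for rid, p in sorted(spec.prevalence.items())
                  if rng.random() < p}

    delivers = ga_days >= 41 * 7
    if delivers:
        delivery_date = preg.edd + timedelta(days=int(rng.integers(-7, 8)))
    else:
        delivery_date = None

    # attended windows: Bernoulli per window whose midpoint has been reached
    cutoff = min(spec.as_of, delivery_date or spec.as_of)
    eligible = []
    for window in schedule.windows:
        start, end = window.dates(lmp)
        midpoint = start + (end - start) / 2
        if midpoint < cutoff:
            eligible.append((window, midpoint))
    attended = [(w, d) for (w, d) in eligible
                if rng.random() < spec.attendance]
    if injections and not attended and eligible:
        attended = [eligible[0]]

    injected_codes: dict = {}
    for pattern in injections.values():
        injected_codes.update(pattern)

    for i, (window, visit_date) in enumerate(attended):
        last = i == len(attended) - 1
        visit = anc.start_visit(record, visit_date, template, user=user,
                                now=datetime.combine(visit_date, time(8, 30)))
        weeks = (visit_date - lmp).days // 7
        for item in template.items:
            overrides = {c: v for c, v in injected_codes.items()
                         if c in item.codes} if last else {}
            if not overrides and rng.random() < 0.08:
                category = str(rng.choice(
                    ["patient_refusal", "missing_equipment", "other"]))
                note = "stock-out noted by provider" \
                    if category == "other" else ""
                anc.complete_item(record, visit, item.item_id, template,
                                  deviation=DeviationReason(category, note),
                                  user=user)
                continue
            if item.codes:
                results = _normal_results(rng, item, weeks)
                results.update(overrides)
                anc.complete_item(record, visit, item.item_id, template,
                                  result=results, ruleset=ruleset,
                                  catalog=catalog, user=user)
            else:
                anc.complete_item(record, visit, item.item_id, template,
                                  ruleset=ruleset, user=user)
        summary = anc.finalize_visit(
            record, visit, ruleset, template, catalog=catalog, user=user,
            now=datetime.combine(visit_date, time(11, 0)))
        for f in summary.findings:
            record_agreement(record, visit, f.rule_id, "agree", user,
                             now=datetime.combine(visit_date, time(11, 5)))

    if delivers:
        pattern = str(rng.choice(
            sorted(spec.labor_pattern_mix),
            p=[spec.labor_pattern_mix[k]
               for k in sorted(spec.labor_pattern_mix)]))
        onset = datetime.combine(delivery_date, time(4, 0))
        trace_seed = int(rng.integers(0, 2**31 - 1))
        labor = generate_labor_trace(pattern, trace_seed, onset=onset)
        preg.labor = labor
        delivery_time = onset + timedelta(
            hours=labor.measurements[-1].t + 1.0)
        pp = partograph.start_postpartum(delivery_time)
        if rng.random() < 0.8:  # most women discharged shortly after the gate
            pp.discharge_time = partograph.earliest_discharge(
                delivery_time) + timedelta(hours=float(rng.uniform(0, 6)))
        preg.delivery = DeliveryRecord(
            delivery_time=delivery_time,
            live_birth=bool(rng.random() < 0.97),
            birth_weight_g=int(rng.integers(2300, 4300)),
            postpartum=pp)
    return record


def generate_cohort(spec: SyntheticSpec, *, ruleset=None, template=None,
                    schedule=None, catalog=None) -> list:
    """Reproducible cohort of patient records for a given seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shared = dict(ruleset=ruleset, template=template, schedule=schedule,
                  catalog=catalog)
    return [generate_patient(spec, i, rng, **shared)
            for i in range(spec.n_patients)]


def write_store(records, directory, *, as_of: Optional[date] = None
                ) -> RecordStore:
    """Materialize records as a patient-XML store directory."""
    store = RecordStore(directory, today=as_of)
    for record in records:
        store.add(record)
    return store
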