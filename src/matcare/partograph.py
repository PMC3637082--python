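"""Electronic partograph: labor-trace monitoring and the postpartum window.

Line geometry follows the WHO composite partograph: the *alert line*
rises from 4 cm at active-phase onset by 1 cm per hour until full
dilatation (10 cm); the *action line* runs parallel, offset 4 hours to
the right.  Both are configurable.

Boundary conventions (documented here on purpose, they decide the worked
examples): a point ON the alert line is still normal — crossing is
strict — while a point ON the action line counts as crossed.  Time ``t``
is measured in hours from active-phase onset (the first measurement with
dilatation at or above the onset threshold), not from facility arrival.
Latent-phase entries (dilatation below the onset threshold) are stored
but never classified against the lines.

After delivery a similar monitored graph follows the mother for 24 hours;
discharge is gated on that window.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional

from .errors import DischargeTooEarly, DomainError, ValidationError
from .knowledge import RuleSet, TranslationCatalog
from .model import LaborSession, Measurement, PostpartumSession


@dataclass(frozen=True)
class PartographConfig:
    """Geometry and monitoring parameters of the partograph.

    onset_dilatation   cm at which the active phase (and the alert line) starts
    line_slope         expected progress, cm per hour
    action_offset      hours between the alert and action lines
    full_dilatation    cm at which labor is complete
    fhr_low/fhr_high   normal fetal-heart-rate band, bpm
    postpartum_window  monitored hours after delivery before discharge
    """

    onset_dilatation: float = 4.0
    line_slope: float = 1.0
    action_offset: float = 4.0
    full_dilatation: float = 10.0
    fhr_low: float = 120.0
    fhr_high: float = 160.0
    postpartum_window: float = 24.0

    def __post_init__(self):
        if self.onset_dilatation >= self.full_dilatation:
            raise ValidationError("onset dilatation must be below full")
        if self.line_slope <= 0 or self.action_offset <= 0:
            raise ValidationError("line slope and action offset must be > 0")


DEFAULT_CONFIG = PartographConfig()


@dataclass(frozen=True)
class ZoneClassification:
    zone: str  # normal | alert | action
    t: float
    dilatation: float
    alert_line: float
    action_line: Optional[float]  # None while the action zone is unreachable


@dataclass(frozen=True)
class LaborPrompt:
    """A message the partograph raises while replaying a trace."""

    kind: str  # alert_entry | action_crossed | watchdog
    t: float
    message: str
    rule_id: str = ""


@dataclass
class LaborEvaluation:
    zones: list  # ZoneClassification per classified measurement
    prompts: list  # of LaborPrompt, in trace order

    def first_action_time(self) -> Optional[float]:
        for z in self.zones:
            if z.zone == "action":
                return z.t
        return None


def alert_line(config: PartographConfig, t: float) -> float:
    """Dilatation expected on the alert line at ``t`` hours after onset."""
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    return min(config.onset_dilatation + config.line_slope * t,
               config.full_dilatation)


def action_line(config: PartographConfig, t: float) -> Optional[float]:
    """Action-line value: the alert line shifted ``action_offset`` hours.

    Undefined (``None``) before the offset — the action zone is
    unreachable there.
    """
    if t < config.action_offset:
        return None
    return alert_line(config, t - config.action_offset)


def classify_point(config: PartographConfig, t: float,
                   d: float) -> ZoneClassification:
    """Zone of one (time, dilatation) point against both lines."""
    al = alert_line(config, t)
    ac = action_line(config, t)
    if ac is not None and d <= ac:
        zone = "action"
    elif d < al:
        zone = "alert"
    else:
        zone = "normal"
    return ZoneClassification(zone=zone, t=t, dilatation=d,
                              alert_line=al, action_line=ac)


def _localize(catalog, key, language):
    if catalog is None:
        return key
    return catalog.translate(key, language)


def evaluate_labor(session: LaborSession,
                   config: PartographConfig = DEFAULT_CONFIG, *,
                   ruleset: Optional[RuleSet] = None,
                   catalog: Optional[TranslationCatalog] = None,
                   language: Optional[str] = None) -> LaborEvaluation:
    """Replay a labor trace: zone per measurement plus raised prompts.

    The first transition into the alert zone raises a detailed-instruction
    prompt; each transition into the action zone raises an urgent prompt.
    A fetal heart rate outside the configured band raises a watchdog at
    that measurement (via the shipped FHR rule when a rule set is given).
    """
    zones: list = []
    prompts: list = []
    alert_raised = False
    prev_zone = "normal"
    last_t = None
    for m in session.measurements:
        if last_t is not None and m.t <= last_t:
            raise ValidationError(
                f"measurement times must strictly increase (t={m.t})")
        last_t = m.t
        if m.dilatation < config.onset_dilatation:
            continue  # latent phase: stored, not classified
        z = classify_point(config, m.t, m.dilatation)
        zones.append(z)
        if z.zone == "alert" and not alert_raised:
            prompts.append(LaborPrompt(
                kind="alert_entry", t=m.t,
                message=_localize(catalog, "partograph.alert_entry",
                                  language)))
            alert_raised = True
        if z.zone == "action" and prev_zone != "action":
            prompts.append(LaborPrompt(
                kind="action_crossed", t=m.t,
                message=_localize(catalog, "partograph.action_crossed",
                                  language)))
        prev_zone = z.zone

        if m.fhr is not None:
            fhr_rules = []
            if ruleset is not None:
                state = {"fetal_heart_rate": m.fhr, **m.vitals}
                from .engine import rule_satisfied
                for rule in ruleset.watchdogs():
                    if "fetal_heart_rate" in _rule_codes(rule) \
                            and rule_satisfied(rule, state):
                        fhr_rules.append(rule)
                for rule in fhr_rules:
                    prompts.append(LaborPrompt(
                        kind="watchdog", t=m.t,
                        message=_localize(catalog, rule.message_key,
                                          language),
                        rule_id=rule.rule_id))
            elif not config.fhr_low <= m.fhr <= config.fhr_high:
                prompts.append(LaborPrompt(
                    kind="watchdog", t=m.t,
                    message=f"fetal heart rate {m.fhr:g} bpm outside "
                            f"[{config.fhr_low:g}, {config.fhr_high:g}]",
                    rule_id="fhr_abnormal"))
    return LaborEvaluation(zones=zones, prompts=prompts)


def _rule_codes(rule):
    from .knowledge import condition_codes
    return condition_codes(rule.condition)


# ---------------------------------------------------------------- trace I/O

TRACE_COLUMNS = ("t_hours", "dilatation_cm", "fhr_bpm")


def read_trace(path, *, onset: Optional[datetime] = None) -> LaborSession:
    """Load a labor trace from delimited text.

    Columns ``t_hours``, ``dilatation_cm``, optional ``fhr_bpm``; any
    further numeric columns are kept as vitals keyed by column name.
    """
    session = LaborSession(active_phase_onset=onset
                           or datetime(2000, 1, 1, 0, 0))
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                not {"t_hours", "dilatation_cm"} <= set(reader.fieldnames):
            raise ValidationError(
                f"trace {path} must have columns t_hours, dilatation_cm")
        extras = [c for c in reader.fieldnames if c not in TRACE_COLUMNS]
        for row in reader:
            fhr = row.get("fhr_bpm")
            session.measurements.append(Measurement(
                t=float(row["t_hours"]),
                dilatation=float(row["dilatation_cm"]),
                fhr=float(fhr) if fhr not in (None, "") else None,
                vitals={c: float(row[c]) for c in extras
                        if row.get(c) not in (None, "")}))
    return session


def write_trace(session: LaborSession, path) -> None:
    vital_cols = sorted({c for m in session.measurements for c in m.vitals})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(TRACE_COLUMNS) + vital_cols)
        for m in session.measurements:
            row = [f"{m.t:g}", f"{m.dilatation:g}",
                   "" if m.fhr is None else f"{m.fhr:g}"]
            row += [f"{m.vitals[c]:g}" if c in m.vitals else ""
                    for c in vital_cols]
            writer.writerow(row)


def plot_partograph(session: LaborSession,
                    config: PartographConfig = DEFAULT_CONFIG,
                    path=None):
    """Render the dilatation trace with both reference lines (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t_full = (config.full_dilatation - config.onset_dilatation) \
        / config.line_slope
    t_max = max([t_full + config.action_offset]
                + [m.t for m in session.measurements]) + 1
    ts = [t_max * i / 200 for i in range(201)]
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.plot(ts, [alert_line(config, t) for t in ts], "y-", label="alert line")
    ats = [t for t in ts if t >= config.action_offset]
    ax.plot(ats, [action_line(config, t) for t in ats], "r-",
            label="action line")
    ax.plot([m.t for m in session.measurements],
            [m.dilatation for m in session.measurements], "ko-",
            label="cervical dilatation")
    ax.set_xlabel("hours since active-phase onset")
    ax.set_ylabel("dilatation (cm)")
    ax.set_ylim(0, config.full_dilatation + 0.5)
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


# --------------------------------------------------------------- postpartum

#: dense early monitoring, then hourly: every 15 min for the first
#: ``dense_hours``, hourly afterwards until the window closes
POSTPARTUM_DENSE_HOURS = 2.0
POSTPARTUM_DENSE_STEP_MIN = 15


def start_postpartum(delivery_time: datetime,
                     config: PartographConfig = DEFAULT_CONFIG
                     ) -> PostpartumSession:
    """Open the postpartum graph with its observation schedule.

    Every 15 minutes for the first 2 hours, then hourly through the end of
    the postpartum window (24 h by default).
    """
    times = []
    t = delivery_time
    dense_end = delivery_time + timedelta(hours=POSTPARTUM_DENSE_HOURS)
    window_end = delivery_time + timedelta(hours=config.postpartum_window)
    while t <= min(dense_end, window_end):
        times.append(t)
        t += timedelta(minutes=POSTPARTUM_DENSE_STEP_MIN)
    t = dense_end + timedelta(hours=1)
    while t <= window_end:
        times.append(t)
        t += timedelta(hours=1)
    return PostpartumSession(delivery_time=delivery_time,
                             scheduled_times=times)


def earliest_discharge(delivery_time: datetime,
                       config: PartographConfig = DEFAULT_CONFIG) -> datetime:
    """Gate: discharge must not happen before the postpartum window ends."""
    return delivery_time + timedelta(hours=config.postpartum_window)


def discharge(session: PostpartumSession, at: datetime,
              config: PartographConfig = DEFAULT_CONFIG) -> PostpartumSession:
    """Record discharge, enforcing the earliest-discharge gate."""
    gate = earliest_discharge(session.delivery_time, config)
    if at < gate:
        remaining = (gate - at).total_seconds() / 3600.0
        raise DischargeTooEarly(remaining)
    if session.discharge_time is not None:
        raise DomainError("discharge already recorded")
    session.discharge_time = at
    return session
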