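"""Core data model for longitudinal maternal-care records.

Plain dataclasses, no behaviour beyond light derived helpers.  Everything
here is persisted to per-patient XML files (see :mod:`matcare.xmlio`) and
manipulated through the workflow modules (:mod:`matcare.records`,
:mod:`matcare.anc`, :mod:`matcare.partograph`).

Dates are naive local calendar dates and timestamps: the system models a
single facility, so no time-zone arithmetic is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Optional, Union

ObsValue = Union[int, float, bool, str]

#: Pregnancy duration used to derive the expected delivery date from the
#: last menstrual period (Naegele-equivalent rule).
GESTATION_DAYS = 280


@dataclass
class Observation:
    """A single coded clinical measurement or sign.

    ``code`` must come from the controlled vocabulary shipped with the
    rule set; numeric values carry a unit.
    """

    code: str
    value: ObsValue
    unit: str = ""
    observed_at: Optional[datetime] = None


@dataclass
class AuditEntry:
    """One line of the per-record audit trail: who did what, when."""

    time: datetime
    user: str
    action: str


@dataclass
class DeviationReason:
    """Why a critical checklist item was not carried out.

    ``category`` is one of ``patient_refusal``, ``missing_equipment`` or
    ``other``; a free-text note is mandatory for ``other``.
    """

    category: str
    note: str = ""


DEVIATION_CATEGORIES = ("patient_refusal", "missing_equipment", "other")


@dataclass
class ItemState:
    """State of one checklist item within a visit."""

    status: str = "pending"  # pending | done | not_done
    results: Optional[dict] = None  # code -> value for done observation items
    deviation: Optional[DeviationReason] = None
    completed_at: Optional[datetime] = None
    user: str = ""


@dataclass
class Alert:
    """Instant 'watch dog' warning fired the moment an abnormal value is entered."""

    rule_id: str
    fired_at: datetime
    triggering_codes: tuple
    message: str
    tier: str = "instant_watchdog"


@dataclass
class Finding:
    """End-of-visit integrated finding with proposed actions and source link.

    ``agreement`` starts ``unset``; the provider records agree/disagree on
    the visit summary page.  Disagreement never blocks care.
    """

    rule_id: str
    message: str
    proposed_actions: tuple = ()  # of (action_kind, localized description)
    source_document_id: str = ""
    source_section: str = ""
    agreement: str = "unset"  # unset | agree | disagree
    agreed_by: str = ""
    agreed_at: Optional[datetime] = None
    evaluated_at: Optional[datetime] = None


@dataclass
class ANCVisit:
    """One checklist-structured antenatal encounter."""

    visit_number: int
    date: date
    item_states: dict = field(default_factory=dict)  # item_id -> ItemState
    observations: list = field(default_factory=list)  # of Observation
    alerts: list = field(default_factory=list)  # of Alert
    findings: list = field(default_factory=list)  # of Finding
    finalized: bool = False
    #: set by finalize_visit while agreements are still outstanding
    finalization_pending: bool = False


@dataclass
class Measurement:
    """One timed intrapartum entry: hours since active-phase onset,
    cervical dilatation (cm), fetal heart rate (bpm), optional vitals."""

    t: float
    dilatation: float
    fhr: Optional[float] = None
    vitals: dict = field(default_factory=dict)  # code -> numeric value


@dataclass
class LaborSession:
    """Timed series of intrapartum measurements for partograph evaluation."""

    active_phase_onset: datetime
    measurements: list = field(default_factory=list)  # of Measurement


@dataclass
class PostpartumSession:
    """Observation schedule and entries covering the monitored window after
    delivery (24 h by default); discharge is gated on that window."""

    delivery_time: datetime
    scheduled_times: list = field(default_factory=list)  # of datetime
    observations: list = field(default_factory=list)  # of Observation
    discharge_time: Optional[datetime] = None


@dataclass
class DeliveryRecord:
    delivery_time: datetime
    live_birth: bool = True
    birth_weight_g: Optional[int] = None
    postpartum: Optional[PostpartumSession] = None


@dataclass
class Pregnancy:
    """One pregnancy episode: LMP/EDD, ordered ANC visits, optional labor
    session and delivery.  A pregnancy is *open* until a delivery is recorded."""

    lmp: date
    edd: date
    visits: list = field(default_factory=list)  # of ANCVisit
    labor: Optional[LaborSession] = None
    delivery: Optional[DeliveryRecord] = None

    @property
    def open(self) -> bool:
        return self.delivery is None


@dataclass
class PatientRecord:
    """Longitudinal obstetric record for one woman."""

    patient_id: str
    name: str
    age: int
    gravidity: int
    parity: int
    pregnancies: list = field(default_factory=list)  # of Pregnancy
    audit_log: list = field(default_factory=list)  # of AuditEntry

    def open_pregnancy(self) -> Optional[Pregnancy]:
        for p in self.pregnancies:
            if p.open:
                return p
        return None

    def current_visits(self) -> list:
        p = self.open_pregnancy()
        return p.visits if p is not None else []
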