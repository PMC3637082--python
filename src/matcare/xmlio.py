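"""XML persistence for patient records and the directory-based store.

One file per patient.  Serialization is canonical: element and attribute
order is fixed, values have one textual form each, so saving an unchanged
record twice yields byte-identical files — which makes the store
diff-friendly and lets tests assert round-trip stability.

Loading is strict by default: unknown elements or a foreign schema version
are rejected.  Lenient mode collects them as warnings instead, for forward
compatibility with records written by newer versions.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from datetime import date, datetime
from pathlib import Path
from typing import Optional

from .errors import DuplicatePatientId, StoreIOError, ValidationError
from .model import (
    Alert,
    ANCVisit,
    AuditEntry,
    DeliveryRecord,
    DeviationReason,
    Finding,
    ItemState,
    LaborSession,
    Measurement,
    Observation,
    PatientRecord,
    PostpartumSession,
    Pregnancy,
)
from .records import validate_record

SCHEMA_VERSION = "1.0"
INDEX_FILE = "index.tsv"


# ---------------------------------------------------------------- value codec

def _fmt_value(v):
    """Canonical (kind, text) pair for a typed observation value."""
    if isinstance(v, bool):
        return "bool", "true" if v else "false"
    if isinstance(v, int):
        return "int", str(v)
    if isinstance(v, float):
        return "float", repr(v)
    return "str", str(v)


def _parse_value(kind: str, text: str):
    if kind == "bool":
        return text == "true"
    if kind == "int":
        return int(text)
    if kind == "float":
        return float(text)
    return text


def _fmt_float(x) -> str:
    return repr(float(x))


def _dt(ts: Optional[datetime]) -> str:
    return ts.isoformat() if ts is not None else ""


def _parse_dt(text: str) -> Optional[datetime]:
    return datetime.fromisoformat(text) if text else None


# ---------------------------------------------------------------- serializer

def _observation_el(parent, tag, obs: Observation):
    kind, text = _fmt_value(obs.value)
    el = ET.SubElement(parent, tag, code=obs.code, kind=kind, value=text,
                       unit=obs.unit, time=_dt(obs.observed_at))
    return el


def record_to_element(record: PatientRecord) -> ET.Element:
    root = ET.Element("patient", id=record.patient_id,
                      schema_version=SCHEMA_VERSION)
    ET.SubElement(root, "demographics", name=record.name,
                  age=str(record.age), gravidity=str(record.gravidity),
                  parity=str(record.parity))
    for preg in record.pregnancies:
        pel = ET.SubElement(root, "pregnancy", lmp=preg.lmp.isoformat(),
                            edd=preg.edd.isoformat())
        for visit in preg.visits:
            vel = ET.SubElement(
                pel, "visit", number=str(visit.visit_number),
                date=visit.date.isoformat(),
                finalized="true" if visit.finalized else "false",
                pending_agreement="true" if visit.finalization_pending else "false")
            for item_id in sorted(visit.item_states):
                st = visit.item_states[item_id]
                attrs = {"id": item_id, "status": st.status,
                         "time": _dt(st.completed_at), "user": st.user}
                if st.deviation is not None:
                    attrs["reason"] = st.deviation.category
                    attrs["note"] = st.deviation.note
                iel = ET.SubElement(vel, "item", attrs)
                for code in sorted(st.results or {}):
                    kind, text = _fmt_value(st.results[code])
                    ET.SubElement(iel, "result", code=code, kind=kind,
                                  value=text)
            for obs in visit.observations:
                _observation_el(vel, "observation", obs)
            for alert in visit.alerts:
                ael = ET.SubElement(vel, "alert", rule=alert.rule_id,
                                    time=_dt(alert.fired_at),
                                    codes=" ".join(alert.triggering_codes))
                ael.text = alert.message
            for f in visit.findings:
                fel = ET.SubElement(vel, "finding", rule=f.rule_id,
                                    agreement=f.agreement, user=f.agreed_by,
                                    agreed=_dt(f.agreed_at),
                                    evaluated=_dt(f.evaluated_at))
                mel = ET.SubElement(fel, "message")
                mel.text = f.message
                for kind, desc in f.proposed_actions:
                    act = ET.SubElement(fel, "action", kind=kind)
                    act.text = desc
                ET.SubElement(fel, "source", document=f.source_document_id,
                              section=f.source_section)
        if preg.labor is not None:
            lel = ET.SubElement(pel, "labor",
                                onset=preg.labor.active_phase_onset.isoformat())
            for m in preg.labor.measurements:
                attrs = {"t": _fmt_float(m.t),
                         "dilatation": _fmt_float(m.dilatation)}
                if m.fhr is not None:
                    attrs["fhr"] = _fmt_float(m.fhr)
                mel = ET.SubElement(lel, "measurement", attrs)
                for code in sorted(m.vitals):
                    ET.SubElement(mel, "vital", code=code,
                                  value=_fmt_float(m.vitals[code]))
        if preg.delivery is not None:
            d = preg.delivery
            attrs = {"time": d.delivery_time.isoformat(),
                     "live_birth": "true" if d.live_birth else "false"}
            if d.birth_weight_g is not None:
                attrs["birth_weight_g"] = str(d.birth_weight_g)
            del_el = ET.SubElement(pel, "delivery", attrs)
            if d.postpartum is not None:
                pp = d.postpartum
                ppel = ET.SubElement(
                    del_el, "postpartum",
                    delivery_time=pp.delivery_time.isoformat(),
                    discharge=_dt(pp.discharge_time))
                for ts in pp.scheduled_times:
                    ET.SubElement(ppel, "scheduled", time=ts.isoformat())
                for obs in pp.observations:
                    _observation_el(ppel, "observation", obs)
    audit_el = ET.SubElement(root, "audit")
    for entry in record.audit_log:
        eel = ET.SubElement(audit_el, "entry", time=entry.time.isoformat(),
                            user=entry.user)
        eel.text = entry.action
    return root


def save_record(record: PatientRecord, destination=None, *,
                today: Optional[date] = None) -> bytes:
    """Validate and serialize; returns the canonical bytes.

    If ``destination`` is given the bytes are written there; nothing is
    written when validation fails.
    """
    issues = validate_record(record, today=today)
    if issues:
        raise ValidationError(
            f"record {record.patient_id!r} fails validation", issues)
    root = record_to_element(record)
    tree = ET.ElementTree(root)
    ET.indent(tree, space="  ")
    data = ET.tostring(root, encoding="unicode", xml_declaration=True)
    payload = (data + "\n").encode("utf-8")
    if destination is not None:
        try:
            Path(destination).write_bytes(payload)
        except OSError as exc:
            raise StoreIOError(f"cannot write {destination}: {exc}",
                               path=str(destination)) from exc
    return payload


# ------------------------------------------------------------------ loader

_KNOWN = {
    "patient": {"demographics", "pregnancy", "audit"},
    "pregnancy": {"visit", "labor", "delivery"},
    "visit": {"item", "observation", "alert", "finding"},
    "item": {"result"},
    "finding": {"message", "action", "source"},
    "labor": {"measurement"},
    "measurement": {"vital"},
    "delivery": {"postpartum"},
    "postpartum": {"scheduled", "observation"},
    "audit": {"entry"},
    "demographics": set(), "observation": set(), "alert": set(),
    "result": set(), "message": set(), "action": set(), "source": set(),
    "vital": set(), "scheduled": set(), "entry": set(),
}


def _check_children(el: ET.Element, lenient: bool, warnings: list):
    known = _KNOWN.get(el.tag, set())
    for child in el:
        if child.tag not in known:
            msg = f"unknown element <{child.tag}> inside <{el.tag}>"
            if lenient:
                warnings.append(msg)
            else:
                raise ValidationError(msg)
        else:
            _check_children(child, lenient, warnings)


def _load_observation(el: ET.Element) -> Observation:
    return Observation(code=el.get("code"),
                       value=_parse_value(el.get("kind"), el.get("value")),
                       unit=el.get("unit", ""),
                       observed_at=_parse_dt(el.get("time", "")))


def load_record(source, *, lenient: bool = False,
                warnings: Optional[list] = None) -> PatientRecord:
    """Parse one patient XML file (path, or bytes/str of XML)."""
    if warnings is None:
        warnings = []
    if isinstance(source, bytes):
        text = source.decode("utf-8")
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        text = source
    else:
        try:
            text = Path(source).read_text(encoding="utf-8")
        except OSError as exc:
            raise StoreIOError(f"cannot read {source}: {exc}",
                               path=str(source)) from exc
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ValidationError(
            f"malformed XML at line {line}, column {col}: {exc}") from exc

    if root.tag != "patient":
        raise ValidationError(f"expected root <patient>, got <{root.tag}>")
    version = root.get("schema_version", "")
    if version != SCHEMA_VERSION:
        msg = f"schema version {version!r} not supported (expect {SCHEMA_VERSION})"
        if lenient:
            warnings.append(msg)
        else:
            raise ValidationError(msg)
    _check_children(root, lenient, warnings)

    demo = root.find("demographics")
    if demo is None:
        raise ValidationError("missing <demographics> element")
    record = PatientRecord(
        patient_id=root.get("id", ""), name=demo.get("name", ""),
        age=int(demo.get("age")), gravidity=int(demo.get("gravidity")),
        parity=int(demo.get("parity")))

    for pel in root.findall("pregnancy"):
        preg = Pregnancy(lmp=date.fromisoformat(pel.get("lmp")),
                         edd=date.fromisoformat(pel.get("edd")))
        for vel in pel.findall("visit"):
            visit = ANCVisit(
                visit_number=int(vel.get("number")),
                date=date.fromisoformat(vel.get("date")),
                finalized=vel.get("finalized") == "true",
                finalization_pending=vel.get("pending_agreement") == "true")
            for iel in vel.findall("item"):
                st = ItemState(status=iel.get("status"),
                               completed_at=_parse_dt(iel.get("time", "")),
                               user=iel.get("user", ""))
                if iel.get("reason") is not None:
                    st.deviation = DeviationReason(iel.get("reason"),
                                                   iel.get("note", ""))
                results = {r.get("code"): _parse_value(r.get("kind"),
                                                       r.get("value"))
                           for r in iel.findall("result")}
                st.results = results or None
                visit.item_states[iel.get("id")] = st
            for oel in vel.findall("observation"):
                visit.observations.append(_load_observation(oel))
            for ael in vel.findall("alert"):
                visit.alerts.append(Alert(
                    rule_id=ael.get("rule"),
                    fired_at=_parse_dt(ael.get("time", "")),
                    triggering_codes=tuple((ael.get("codes") or "").split()),
                    message=ael.text or ""))
            for fel in vel.findall("finding"):
                src = fel.find("source")
                visit.findings.append(Finding(
                    rule_id=fel.get("rule"),
                    message=(fel.findtext("message") or ""),
                    proposed_actions=tuple((a.get("kind"), a.text or "")
                                           for a in fel.findall("action")),
                    source_document_id=src.get("document") if src is not None else "",
                    source_section=src.get("section") if src is not None else "",
                    agreement=fel.get("agreement", "unset"),
                    agreed_by=fel.get("user", ""),
                    agreed_at=_parse_dt(fel.get("agreed", "")),
                    evaluated_at=_parse_dt(fel.get("evaluated", ""))))
            preg.visits.append(visit)
        lel = pel.find("labor")
        if lel is not None:
            labor = LaborSession(
                active_phase_onset=datetime.fromisoformat(lel.get("onset")))
            for mel in lel.findall("measurement"):
                fhr = mel.get("fhr")
                labor.measurements.append(Measurement(
                    t=float(mel.get("t")),
                    dilatation=float(mel.get("dilatation")),
                    fhr=float(fhr) if fhr is not None else None,
                    vitals={v.get("code"): float(v.get("value"))
                            for v in mel.findall("vital")}))
            preg.labor = labor
        del_el = pel.find("delivery")
        if del_el is not None:
            bw = del_el.get("birth_weight_g")
            delivery = DeliveryRecord(
                delivery_time=datetime.fromisoformat(del_el.get("time")),
                live_birth=del_el.get("live_birth") == "true",
                birth_weight_g=int(bw) if bw is not None else None)
            ppel = del_el.find("postpartum")
            if ppel is not None:
                pp = PostpartumSession(
                    delivery_time=datetime.fromisoformat(
                        ppel.get("delivery_time")),
                    discharge_time=_parse_dt(ppel.get("discharge", "")))
                pp.scheduled_times = [
                    datetime.fromisoformat(s.get("time"))
                    for s in ppel.findall("scheduled")]
                pp.observations = [_load_observation(o)
                                   for o in ppel.findall("observation")]
                delivery.postpartum = pp
            preg.delivery = delivery
        record.pregnancies.append(preg)

    audit_el = root.find("audit")
    if audit_el is not None:
        for eel in audit_el.findall("entry"):
            record.audit_log.append(AuditEntry(
                time=datetime.fromisoformat(eel.get("time")),
                user=eel.get("user", ""), action=eel.text or ""))
    return record


# ------------------------------------------------------------------- store

def _filename(patient_id: str) -> str:
    safe = "".join(c if c.isalnum() or c in "-_." else "_"
                   for c in patient_id)
    return f"{safe}.xml"


class RecordStore:
    """A directory of per-patient XML files plus a tab-separated index.

    Patient ids are unique within a store; :meth:`add` rejects collisions.
    """

    def __init__(self, directory, *, today: Optional[date] = None):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.today = today
        self._index: dict = {}
        self._read_index()

    def _read_index(self) -> None:
        path = self.directory / INDEX_FILE
        if path.exists():
            for line in path.read_text(encoding="utf-8").splitlines():
                if line.strip():
                    pid, fname = line.split("\t")
                    self._index[pid] = fname

    def _write_index(self) -> None:
        lines = [f"{pid}\t{self._index[pid]}"
                 for pid in sorted(self._index)]
        (self.directory / INDEX_FILE).write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")

    def patient_ids(self) -> list:
        return sorted(self._index)

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self._index

    def __len__(self) -> int:
        return len(self._index)

    def add(self, record: PatientRecord) -> Path:
        if record.patient_id in self._index:
            raise DuplicatePatientId(
                f"patient id {record.patient_id!r} already exists in store")
        return self.save(record, _new=True)

    def save(self, record: PatientRecord, _new: bool = False) -> Path:
        if not _new and record.patient_id not in self._index:
            raise StoreIOError(
                f"patient {record.patient_id!r} not in store; use add()",
                path=str(self.directory))
        fname = _filename(record.patient_id)
        path = self.directory / fname
        save_record(record, path, today=self.today)
        self._index[record.patient_id] = fname
        self._write_index()
        return path

    def load(self, patient_id: str, *, lenient: bool = False,
             warnings: Optional[list] = None) -> PatientRecord:
        if patient_id not in self._index:
            raise StoreIOError(f"no such patient {patient_id!r}",
                               path=str(self.directory))
        return load_record(self.directory / self._index[patient_id],
                           lenient=lenient, warnings=warnings)

    def __iter__(self):
        for pid in self.patient_ids():
            yield self.load(pid)
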