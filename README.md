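# matcare

Rule-based clinical decision support for rural antenatal and intrapartum
care, built for settings where maternity units are staffed by nurses and
midwives without physicians on site. The package provides, as a Python
library with a thin command-line wrapper:

- a **longitudinal obstetric patient record** (pregnancies → visits →
  coded observations) with canonical per-patient **XML persistence** and a
  directory-based store — repeated saves of an unchanged record are
  byte-identical;
- a **declarative guideline rule engine**: rules are data (YAML), each a
  condition tree of predicates over a controlled observation vocabulary,
  split into instant *watch-dog* alerts (fired the moment an abnormal
  value is entered) and *end-of-visit* integration rules that combine
  history, examination and laboratory data across visits — e.g. elevated
  blood pressure + proteinuria and/or blurred vision → "consider
  preeclampsia", with proposed actions and a resolvable guideline source
  link. Providers record agreement or disagreement with each finding;
  disagreement never blocks care;
- a **checklist-guided ANC workflow** (history, examination, laboratory,
  counselling, preventive measures) where critical items must be done or
  carry a documented deviation reason (patient refusal, missing
  equipment, other + note), plus focused-ANC visit scheduling and
  automatic **overdue detection**;
- an **electronic partograph**: cervical-dilatation traces evaluated
  against the WHO composite geometry, and a postpartum graph through
  24 h with an earliest-discharge gate;
- a seeded **synthetic cohort generator** so every component is testable
  without any patient data;
- a **translation catalog** (English default, French and Kiswahili
  shipped, fallback to the default language) and a **document registry**
  whose training materials are open-access, no password required.

## The partograph model

With dilatation d (cm) and t hours since active-phase onset, the alert
line is `A(t) = min(D0 + s·t, F)` with onset dilatation `D0 = 4` cm,
slope `s = 1` cm/h and full dilatation `F = 10` cm; the action line is
the alert line shifted `Δ = 4` h right, `B(t) = A(t − Δ)` for `t ≥ Δ`.
A point is in the **action** zone when `d ≤ B(t)` (on the line counts as
crossed), in the **alert** zone when `d < A(t)` (on the alert line is
still normal), otherwise **normal**. A stalled trace — 4 cm at onset,
6 cm at 2 h, no further progress — is therefore in the alert zone at the
4-h mark and first crosses the action line at the 6-h mark.

## Worked example

`python examples/partograph_replay.py` replays the stalled labor above:

```
t= 0.0 h  d= 4.0 cm  alert= 4.0  action=   -  zone=normal
t= 2.0 h  d= 6.0 cm  alert= 6.0  action=   -  zone=normal
t= 3.0 h  d= 6.0 cm  alert= 7.0  action=   -  zone=alert
      >> [alert_entry] Labour progress has crossed the alert line: ...
t= 4.0 h  d= 6.0 cm  alert= 8.0  action= 4.0  zone=alert
t= 5.0 h  d= 6.0 cm  alert= 9.0  action= 5.0  zone=alert
t= 6.0 h  d= 6.0 cm  alert=10.0  action= 6.0  zone=action
      >> [action_crossed] URGENT: the action line has been crossed - ...
t= 7.0 h  d= 6.0 cm  alert=10.0  action= 7.0  zone=action

action line first crossed at t=6 h
```

Each line shows the measured dilatation against both reference lines; the
prompts are the decision support a birth attendant would see — detailed
instructions on entering the alert zone, an urgent referral prompt when
the action line is crossed at 6 h.

The other examples cover a full checklist visit with watchdogs and the
preeclampsia finding (`examples/anc_visit.py`), synthetic cohorts and
prevalence auditing (`examples/synthetic_cohort.py`), and overdue
detection (`examples/overdue_audit.py`). The same capabilities are
scriptable from a shell via the `matcare` command (`matcare --help`):
`register`, `visit`, `finalize`, `partograph`, `overdue`, `synth`,
`validate`, `docs`.

## Layout

```
src/matcare/          library (records, xmlio, knowledge, engine, anc,
                      partograph, synthetic, oracles, cli)
src/matcare/data/     reference rule set, translations, document registry,
                      checklist template, visit schedule (all YAML)
examples/             one narrative script per capability
tests/                pytest suite (unit, property and end-to-end)
docs/methods.md       models, conventions, parameters, limitations
```
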