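# Methods

This note records the models, conventions and parameter choices behind
`matcare`, and what the shipped tests do and do not demonstrate.

## Patient record and XML persistence

A record is one woman with ordered pregnancies; at most one pregnancy is
open (no delivery) at a time. The expected delivery date is
`EDD = LMP + 280 days`, the standard obstetric (Naegele-equivalent)
rule; gestational age is exact integer weeks plus remainder days of the
calendar difference. Dates and timestamps are naive local values — the
system models a single facility, so no time-zone arithmetic exists
anywhere.

Persistence is one XML file per patient plus a tab-separated index in a
store directory. Serialization is canonical: fixed element and attribute
order, one textual form per value (typed via a `kind` attribute:
int/float/bool/str, floats via `repr`), so save→load→save is
byte-identical. That property is what makes the store diff-friendly and
lets the suite assert round-trip stability over whole synthetic cohorts.
Loading is strict by default (unknown elements and foreign schema
versions are rejected); a lenient mode collects them as warnings for
forward compatibility. Patient identifiers are caller-supplied strings —
facility numbering schemes vary — and uniqueness is enforced per store.

Validation separates hard invariant violations (parity > gravidity,
out-of-order visits, future observation timestamps, unitless numeric
values) from clinically-unusual-but-possible warnings (age outside 10–60
years, delivery more than six weeks from the EDD).

## Guideline knowledge as data

Clinical content lives in versioned YAML, never in engine code: a
controlled observation vocabulary (each code typed numeric/boolean/
category, numeric codes carrying units) and rules whose conditions are
finite trees of predicates (`eq ne lt le gt ge present absent`) under
`all`/`any`/`not` combinators. Thresholds in the reference set are the
standard obstetric/guideline values: elevated blood pressure ≥ 140/90
mmHg, severe hypertension ≥ 160/110 mmHg, anaemia Hb < 11 g/dL (severe
< 7), normal fetal heart rate 120–160 bpm, fever ≥ 38.0 °C. Each rule
cites a document in the registry plus a section label; shipped sources
always resolve. The preeclampsia rule is a deliberate conjunction —
elevated BP AND (proteinuria OR blurred vision) — because elevated
pressure is necessary for the diagnosis while either corroborating sign
suffices; the shape is in the rule file so reviewers can change it
without touching the engine.

Rule files load atomically: an unknown code, bad comparator or dangling
key rejects the whole set. `validate_ruleset` additionally brute-forces
each condition over a small per-code value lattice (every mentioned
threshold ± one step, missing, boolean poles) to report unreachable
rules.

Messages route through a translation catalog (default English, French
and Kiswahili shipped). The default language must cover every key;
lookup falls back to it, so `translate` never fails for a known key.
Training documents in the registry are open-access by invariant — they
must be readable without a personal password.

## Rule evaluation

Both tiers evaluate the same state: all observations of the open
pregnancy reduced to the latest value per code (timestamps decide,
entry order breaks ties), so evaluation is invariant under permutation
of entry order, and an end-of-visit rule can integrate a history item
from visit 1 with a lab result from visit 3. Missing data collapses a
predicate to false (`absent` to true); the checklist layer separately
guarantees that critical items were addressed or carry a documented
reason, so "missing" is an audited state rather than a silent one. For
boolean signs, `present` means recorded *and* true: a documented "no
bleeding" is evidence of absence, not presence.

Watchdogs differ from end-of-visit rules only in trigger moment. A
watchdog fires when the newly entered observation participates in the
rule's condition and the condition holds on the updated state: alerts
re-fire on each new triggering entry (there is no per-visit
suppression), but entering an unrelated value never repeats old alerts.
Evaluation is side-effect-free and deterministic; findings are always
recomputed on (re-)finalization, never cached. The production evaluator
compiles condition trees to closures; an independent recursive
interpreter (`matcare.oracles.condition_oracle`) exists purely as a
cross-check, and the suite asserts equivalence of the two on 10⁴
randomized states for every shipped rule.

The engine proposes and never enforces: providers record agreement or
disagreement per finding, with user and time, and disagreement completes
finalization exactly as agreement does. Deliberately withheld data is
out of scope — no software layer can detect values that were never
entered.

## ANC workflow and scheduling

Checklist items move `pending → done` (producing coded observations and
triggering watchdogs at the point of care) or `pending → not_done` with
a deviation reason (`patient_refusal`, `missing_equipment`, or `other`
plus mandatory note). Finalization requires no critical item pending,
runs the integration rules, and holds the visit in a pending state until
every finding has a stance; a visit with no findings finalizes
immediately. Finalized visits are immutable except for agreement
annotations. Every mutating operation appends exactly one audit entry.

The default schedule is the WHO focused-ANC model — four visits at
gestational windows 8–12, 24–26, 30–32 and 36–38 completed weeks — as
deployment-replaceable data, since national schedules differ. A window
maps to calendar dates as `[LMP + 7·start_week, LMP + 7·end_week + 6]`
days. A woman is overdue when the first window with no completed visit
ended before today; delivered pregnancies are excluded. The overdue scan
is cross-checked against an independent brute-force per-patient schedule
walk in the tests.

## Partograph

Geometry (WHO composite partograph, all configurable): alert line from
`D₀ = 4` cm rising `s = 1` cm/h, capped at `F = 10` cm; action line
parallel, `Δ = 4` h to the right. Boundary conventions, chosen once and
used everywhere: **on the alert line is normal** (crossing is strict),
**on the action line counts as crossed**. Time is measured from
active-phase onset, not facility arrival; latent-phase measurements
(d < D₀) are stored but not classified. Under these conventions the
canonical stalled trace (4 cm at onset, 6 cm at 2 h, flat thereafter,
hourly marks) sits in the alert zone at 4 h and first crosses the action
line at 6 h — the two worked numbers the acceptance script recomputes.

Replay raises one detailed-instruction prompt on first alert entry, an
urgent prompt on each transition into the action zone, and a fetal-
heart-rate watchdog per measurement outside 120–160 bpm (through the
shipped FHR rule when a rule set is supplied, else the config band).
Zone classification is cross-checked against direct evaluation of the
two line formulas on an exhaustive grid (t in 0–12 h by 0.25, d in
0–10 cm by 0.5).

The postpartum graph schedules observations every 15 min for 2 h, then
hourly to 24 h (common postnatal practice; configurable), and gates
discharge at `delivery_time + 24 h` exactly; an early attempt fails
naming the remaining hours.

## Synthetic cohorts

The generator drives the real workflow API (register, start visit,
complete items, finalize, agree), so synthetic records have full item
states, alerts, findings and audit trails and always pass validation and
the byte-identical XML round trip. All randomness flows from a single
seeded `numpy` generator; the reference date anchoring gestational ages
is fixed (2024-07-01) so cohorts are reproducible byte-for-byte.

Default conditions, chosen once as plausible for a rural ANC population
and not tuned thereafter: gestational age uniform over 13–44 weeks at
the reference date (women past 41 weeks deliver, with a labor trace and
postpartum session); attendance 0.85 per reached window; danger-sign
prevalences preeclampsia 0.05, anaemia 0.15, fever 0.04, vaginal
bleeding 0.02, abnormal FHR 0.04; labor pattern mix 70% normal / 20%
slow / 10% obstructed; 8% of checklist items not done with a sampled
deviation reason. Injection writes the *complete* observation pattern a
rule needs at one visit (forcing at least one attended visit), so a
configured prevalence maps one-to-one onto the expected finding rate up
to binomial noise — which is exactly what the prevalence-recovery test
checks against the analytic 99% binomial interval.

Labor traces are constructed to guarantee their zone profile under the
default geometry: `normal` never falls below the alert line, `slow`
enters the alert zone but stays strictly above the action line (a slow
phase at 0.4–0.7 cm/h followed by augmented progress), `obstructed`
stalls until the action line is crossed. Dilatation moves in half-
centimetre steps at hourly marks; fetal heart rate stays in band so zone
prompts can be asserted in isolation.

What the generator does **not** emulate: correlated risk factors,
seasonality, measurement error, irregular visit timing within windows,
or adversarial data entry. Passing tests therefore demonstrate engine
and workflow correctness under the stated conditions, not clinical
performance on real cohorts.

## Problem sizes and numerical choices

The suite runs cohorts of 25–1000 patients and 10⁴ randomized rule
states; the end-to-end checks use a 1000-record cohort with 10%
injected preeclampsia at a fixed seed. Dilatation arithmetic is plain
float; zone boundaries use exact comparisons (`≤` action, `<` alert) —
the half-centimetre measurement grid keeps points off pathological
float boundaries. Rule firing order is deterministic: watchdogs before
end-of-visit rules, lexicographic rule id within a tier.

## Known limitations

- The rule inventory covers the reference conditions listed above, not
  the full guideline; clinical completeness is a deployment task (rules
  are data).
- The handwritten ANC card remains the parallel source document;
  printing and multi-facility synchronization are out of scope.
- Access control is an audit-trail user id, not authentication.
- The partograph evaluates dilatation, FHR and supplied vitals; other
  partograph panels (moulding, caput, liquor) can be stored as free
  observations but are not rule-evaluated.
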