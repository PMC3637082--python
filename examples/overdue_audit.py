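"""Find women overdue for antenatal care in a synthetic cohort.

With an 60% attendance model many women miss a scheduled window; the
overdue scan lists every open pregnancy whose next focused-ANC window
(8-12, 24-26, 30-32, 36-38 weeks) ended before today, so they can be
contacted.  Delivered women are excluded: their follow-up belongs to the
postpartum pathway.
"""

from matcare import SyntheticSpec, find_overdue, generate_cohort
from matcare.defaults import default_schedule
from matcare.records import gestational_age

spec = SyntheticSpec(n_patients=40, seed=6, attendance=0.6)
records = generate_cohort(spec)
schedule = default_schedule()
today = spec.as_of

rows = find_overdue(records, today, schedule)
print(f"{len(rows)} of {len(records)} women overdue on {today}:")
for patient_id, window, window_end in rows[:10]:
    record = next(r for r in records if r.patient_id == patient_id)
    ga = gestational_age(record.open_pregnancy().lmp, today)
    print(f"  {patient_id}  GA {ga}  missed visit {window.visit_number} "
          f"(weeks {window.start_week}-{window.end_week}, "
          f"window ended {window_end})")
if len(rows) > 10:
    print(f"  ... and {len(rows) - 10} more")
# Each line is a woman to contact, with the exact window she missed.
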