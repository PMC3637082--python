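"""One antenatal visit, end to end: checklist, watchdogs, integrated findings.

Registers a patient, walks the checklist with the classic preeclampsia
triad (blurred vision in the history, 150/95 mmHg on examination,
protein-positive urine in the lab section), and finalizes the visit.
Watch-dog alerts print the moment the triggering value is entered; the
integrated preeclampsia suggestion appears on the end-of-visit summary
with its guideline source, and the provider's agreement is recorded.
"""

from datetime import date

import matcare as mc

ruleset = mc.default_ruleset()
template = mc.default_template()
catalog = mc.default_catalog()

record = mc.new_record("GH-0042", "Esi", age=28, gravidity=3, parity=2,
                       lmp=date(2024, 1, 1), user="nurse1",
                       today=date(2024, 7, 1))
print(f"registered {record.patient_id}; "
      f"EDD {record.open_pregnancy().edd} (LMP + 280 days)")

visit = mc.start_visit(record, date(2024, 4, 1), template, user="nurse1")
entries = [
    ("record_blurred_vision", True),
    ("record_vaginal_bleeding", False),
    ("measure_bp", {"systolic_bp": 150, "diastolic_bp": 95}),
    ("measure_temperature", 36.9),
    ("auscultate_fhr", 142),
    ("test_haemoglobin", 12.3),
    ("test_proteinuria", True),
    ("test_syphilis", False),
    ("test_hiv", False),
    ("give_tetanus_toxoid", None),
    ("give_ipt_malaria", None),
    ("give_iron_folate", None),
]
for item_id, result in entries:
    alerts = mc.complete_item(record, visit, item_id, template,
                              result=result, ruleset=ruleset,
                              catalog=catalog, user="nurse1")
    for alert in alerts:  # instant decision support at the point of care
        print(f"  WATCHDOG [{alert.rule_id}] {alert.message}")

summary = mc.finalize_visit(record, visit, ruleset, template,
                            catalog=catalog, user="nurse1")
print()
print(summary.to_text())

for finding in visit.findings:
    mc.record_agreement(record, visit, finding.rule_id, "agree", "nurse1")
print(f"\nvisit finalized: {visit.finalized} "
      f"(all findings acknowledged); audit entries: {len(record.audit_log)}")
# The elevated-BP watchdog fires at entry time; the preeclampsia finding
# integrates history + examination + laboratory at the end of the visit.
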