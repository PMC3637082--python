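# Reference antenatal/intrapartum rule set.
#
# Clinical thresholds are guideline-derived (WHO "Pregnancy, Childbirth,
# Postpartum and Newborn Care: A Guide for Essential Practice" and standard
# obstetric definitions) and live HERE, never in engine code, so they can
# be audited and adapted per deployment:
#   - elevated blood pressure: >= 140 mmHg systolic or >= 90 mmHg diastolic
#   - severe hypertension:     >= 160 mmHg systolic or >= 110 mmHg diastolic
#   - anaemia: haemoglobin < 11 g/dL; severe anaemia: < 7 g/dL
#   - normal fetal heart rate band: 120-160 bpm
#   - fever: temperature >= 38.0 C
meta:
  ruleset_version: "1.0"
  guideline: "WHO Pregnancy, Childbirth, Postpartum and Newborn Care: A Guide for Essential Practice"

vocabulary:
  systolic_bp: {kind: numeric, unit: mmHg, label: "Systolic blood pressure"}
  diastolic_bp: {kind: numeric, unit: mmHg, label: "Diastolic blood pressure"}
  temperature_c: {kind: numeric, unit: degC, label: "Body temperature"}
  fetal_heart_rate: {kind: numeric, unit: bpm, label: "Fetal heart rate"}
  haemoglobin: {kind: numeric, unit: g/dL, label: "Haemoglobin"}
  weight_kg: {kind: numeric, unit: kg, label: "Maternal weight"}
  fundal_height_cm: {kind: numeric, unit: cm, label: "Symphysis-fundal height"}
  proteinuria: {kind: boolean, label: "Protein in urine (dipstick positive)"}
  blurred_vision: {kind: boolean, label: "Blurred vision reported"}
  severe_headache: {kind: boolean, label: "Severe headache reported"}
  vaginal_bleeding: {kind: boolean, label: "Vaginal bleeding"}
  oedema: {kind: boolean, label: "Oedema of face or hands"}
  syphilis_positive: {kind: boolean, label: "Syphilis test positive"}
  hiv_positive: {kind: boolean, label: "HIV test positive"}

rules:
  - id: elevated_bp
    severity: instant_watchdog
    message_key: rule.elevated_bp
    condition:
      any:
        - {code: systolic_bp, op: ge, value: 140}
        - {code: diastolic_bp, op: ge, value: 90}
    actions:
      - {kind: exam, description_key: action.recheck_bp}
    source: {document_id: who_pcpnc, section: "Respond to observed signs: elevated blood pressure"}

  - id: severe_hypertension
    severity: instant_watchdog
    message_key: rule.severe_hypertension
    condition:
      any:
        - {code: systolic_bp, op: ge, value: 160}
        - {code: diastolic_bp, op: ge, value: 110}
    actions:
      - {kind: treatment, description_key: action.antihypertensive}
      - {kind: referral, description_key: action.refer_hospital}
    source: {document_id: who_pcpnc, section: "Respond to observed signs: severe hypertension"}

  - id: fhr_abnormal
    severity: instant_watchdog
    message_key: rule.fhr_abnormal
    condition:
      any:
        - {code: fetal_heart_rate, op: lt, value: 120}
        - {code: fetal_heart_rate, op: gt, value: 160}
    actions:
      - {kind: exam, description_key: action.recheck_fhr}
      - {kind: referral, description_key: action.refer_hospital}
    source: {document_id: who_pcpnc, section: "Fetal heart rate outside the normal band"}

  - id: fever
    severity: instant_watchdog
    message_key: rule.fever
    condition: {code: temperature_c, op: ge, value: 38.0}
    actions:
      - {kind: exam, description_key: action.assess_infection}
    source: {document_id: who_pcpnc, section: "Fever in pregnancy"}

  - id: severe_anaemia
    severity: instant_watchdog
    message_key: rule.severe_anaemia
    condition: {code: haemoglobin, op: lt, value: 7.0}
    actions:
      - {kind: referral, description_key: action.refer_hospital}
    source: {document_id: who_pcpnc, section: "Severe anaemia"}

  - id: vaginal_bleeding_danger
    severity: instant_watchdog
    message_key: rule.vaginal_bleeding_danger
    condition: {code: vaginal_bleeding, op: present}
    actions:
      - {kind: exam, description_key: action.assess_bleeding}
      - {kind: referral, description_key: action.refer_hospital}
    source: {document_id: who_pcpnc, section: "Vaginal bleeding danger sign"}

  # Suggest preeclampsia when blood pressure is elevated AND at least one
  # corroborating sign (proteinuria or blurred vision) is present.
  # Elevated BP is necessary: visual symptoms or proteinuria alone have
  # other differentials and do not fire this rule.
  - id: preeclampsia_suspicion
    severity: end_of_visit
    message_key: rule.preeclampsia_suspicion
    condition:
      all:
        - any:
            - {code: systolic_bp, op: ge, value: 140}
            - {code: diastolic_bp, op: ge, value: 90}
        - any:
            - {code: proteinuria, op: present}
            - {code: blurred_vision, op: present}
    actions:
      - {kind: exam, description_key: action.recheck_bp}
      - {kind: referral, description_key: action.preeclampsia_refer}
    source: {document_id: who_pcpnc, section: "Pre-eclampsia and eclampsia"}

  - id: anaemia
    severity: end_of_visit
    message_key: rule.anaemia
    condition: {code: haemoglobin, op: lt, value: 11.0}
    actions:
      - {kind: treatment, description_key: action.iron_folate}
      - {kind: counselling, description_key: action.counsel_nutrition}
    source: {document_id: who_pcpnc, section: "Anaemia in pregnancy"}
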