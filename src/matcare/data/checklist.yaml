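# Reference ANC visit checklist: ordered sections guiding the provider
# step by step through history, examination, laboratory, counselling and
# preventive measures.  Items either produce coded observations (codes
# from the rule-set vocabulary) or record pure actions.  Criticality is a
# property of the template, not of engine logic: a critical item must be
# done or carry a documented deviation reason before finalization.
template_version: "1.0"
sections:
  - name: history
    items:
      - {id: record_blurred_vision, label: "Ask about blurred vision", codes: [blurred_vision]}
      - {id: record_severe_headache, label: "Ask about severe headache", codes: [severe_headache]}
      - {id: record_vaginal_bleeding, label: "Ask about vaginal bleeding", codes: [vaginal_bleeding], critical: true}
  - name: examination
    items:
      - {id: measure_bp, label: "Measure blood pressure", codes: [systolic_bp, diastolic_bp], critical: true}
      - {id: measure_temperature, label: "Measure temperature", codes: [temperature_c]}
      - {id: measure_weight, label: "Weigh the patient", codes: [weight_kg]}
      - {id: measure_fundal_height, label: "Measure symphysis-fundal height", codes: [fundal_height_cm]}
      - {id: check_oedema, label: "Check for oedema of face/hands", codes: [oedema]}
      - {id: auscultate_fhr, label: "Auscultate fetal heart rate", codes: [fetal_heart_rate], critical: true}
  - name: laboratory
    items:
      - {id: test_haemoglobin, label: "Haemoglobin test", codes: [haemoglobin], critical: true}
      - {id: test_proteinuria, label: "Urine dipstick for protein", codes: [proteinuria], critical: true}
      - {id: test_syphilis, label: "Syphilis test", codes: [syphilis_positive], critical: true}
      - {id: test_hiv, label: "HIV test (with consent)", codes: [hiv_positive], critical: true}
  - name: counselling
    items:
      - {id: counsel_birth_plan, label: "Counsel on birth and emergency plan", action: counselling}
      - {id: counsel_danger_signs, label: "Counsel on danger signs", action: counselling}
      - {id: counsel_nutrition, label: "Counsel on nutrition", action: counselling}
  - name: preventive_measures
    items:
      - {id: give_tetanus_toxoid, label: "Tetanus toxoid dose", action: preventive, critical: true}
      - {id: give_ipt_malaria, label: "Intermittent preventive treatment for malaria", action: preventive, critical: true}
      - {id: give_iron_folate, label: "Iron/folate supplementation", action: preventive, critical: true}
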