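# Message catalog.  English is the default language and covers every key;
# French (fr) and Kiswahili (sw) may be partial — lookup falls back to the
# default language for uncovered keys.
default_language: en
messages:
  rule.elevated_bp:
    en: "Elevated blood pressure (>= 140/90 mmHg)."
    fr: "Tension arterielle elevee (>= 140/90 mmHg)."
    sw: "Shinikizo la damu limepanda (>= 140/90 mmHg)."
  rule.severe_hypertension:
    en: "Severe hypertension (>= 160/110 mmHg) - urgent assessment needed."
    fr: "Hypertension severe (>= 160/110 mmHg) - evaluation urgente requise."
    sw: "Shinikizo la damu kali (>= 160/110 mmHg) - tathmini ya haraka inahitajika."
  rule.fhr_abnormal:
    en: "Fetal heart rate outside the normal band of 120-160 bpm."
    fr: "Rythme cardiaque foetal hors de la bande normale de 120-160 bpm."
    sw: "Mapigo ya moyo wa mtoto nje ya kiwango cha kawaida cha 120-160 bpm."
  rule.fever:
    en: "Fever: temperature 38.0 C or higher."
    fr: "Fievre : temperature de 38,0 C ou plus."
  rule.severe_anaemia:
    en: "Severe anaemia: haemoglobin below 7 g/dL."
    fr: "Anemie severe : hemoglobine inferieure a 7 g/dL."
  rule.vaginal_bleeding_danger:
    en: "Vaginal bleeding is a danger sign at any stage of pregnancy."
    fr: "Les saignements vaginaux sont un signe de danger a tout stade de la grossesse."
  rule.preeclampsia_suspicion:
    en: "Consider the diagnosis of preeclampsia: elevated blood pressure with proteinuria and/or blurred vision."
    fr: "Envisager le diagnostic de preeclampsie : tension arterielle elevee avec proteinurie et/ou vision floue."
    sw: "Fikiria utambuzi wa kifafa cha mimba: shinikizo la damu pamoja na protini kwenye mkojo na/au kuona ukungu."
  rule.anaemia:
    en: "Anaemia: haemoglobin below 11 g/dL."
    fr: "Anemie : hemoglobine inferieure a 11 g/dL."
  action.recheck_bp:
    en: "Re-measure blood pressure after 10 minutes of rest."
    fr: "Reprendre la tension arterielle apres 10 minutes de repos."
  action.recheck_fhr:
    en: "Re-auscultate the fetal heart rate; check maternal pulse."
    fr: "Re-ausculter le rythme cardiaque foetal ; verifier le pouls maternel."
  action.antihypertensive:
    en: "Give antihypertensive treatment per guideline."
    fr: "Administrer un traitement antihypertenseur selon le guide."
  action.refer_hospital:
    en: "Refer to the district hospital."
    fr: "Referer a l'hopital de district."
    sw: "Mpeleke kwenye hospitali ya wilaya."
  action.preeclampsia_refer:
    en: "Refer for confirmation and management of preeclampsia."
    fr: "Referer pour confirmation et prise en charge de la preeclampsie."
  action.assess_infection:
    en: "Assess for infection (malaria test, urine, other sources)."
    fr: "Rechercher une infection (test paludisme, urine, autres sources)."
  action.assess_bleeding:
    en: "Assess amount and source of bleeding; do not perform vaginal examination if late pregnancy."
    fr: "Evaluer la quantite et l'origine du saignement ; pas de toucher vaginal en fin de grossesse."
  action.iron_folate:
    en: "Give iron and folate supplementation."
    fr: "Donner une supplementation en fer et folates."
  action.counsel_nutrition:
    en: "Counsel on nutrition and adherence to supplementation."
    fr: "Conseiller sur la nutrition et l'observance de la supplementation."
  partograph.alert_entry:
    en: "Labour progress has crossed the alert line: reassess, prepare for possible referral, follow detailed instructions."
    fr: "La progression du travail a franchi la ligne d'alerte : reevaluer, preparer une eventuelle reference, suivre les instructions detaillees."
    sw: "Uchungu umevuka mstari wa tahadhari: tathmini upya, jiandae kwa rufaa, fuata maelekezo."
  partograph.action_crossed:
    en: "URGENT: the action line has been crossed - immediate action required, refer now unless delivery is imminent."
    fr: "URGENT : la ligne d'action a ete franchie - action immediate requise, referer sauf accouchement imminent."
    sw: "HARAKA: mstari wa hatua umevukwa - hatua ya haraka inahitajika, toa rufaa isipokuwa kujifungua ni karibu."
  partograph.discharge_gate:
    en: "Discharge is not permitted before the end of the postpartum observation window."
    fr: "La sortie n'est pas autorisee avant la fin de la periode d'observation postpartum."
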