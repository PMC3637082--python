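# Document registry: references only (title + location), never document
# text.  Training-category documents are open-access by invariant so they
# can be read without a personal password.
documents:
  - id: who_pcpnc
    title: "Pregnancy, Childbirth, Postpartum and Newborn Care: A Guide for Essential Practice (WHO)"
    location: "https://www.who.int/publications/i/item/9789241549356"
    access_level: open
    category: guideline
  - id: national_anc_guideline
    title: "National antenatal care guideline (district health authority)"
    location: "docs/national_anc_guideline.pdf"
    access_level: open
    category: guideline
  - id: training_partograph
    title: "Using the partograph: self-study module"
    location: "training/partograph_module.pdf"
    access_level: open
    category: training
  - id: training_danger_signs
    title: "Danger signs in pregnancy: refresher slides"
    location: "training/danger_signs.pdf"
    access_level: open
    category: training
  - id: facility_sop
    title: "Facility standard operating procedures (staff only)"
    location: "local/facility_sop.pdf"
    access_level: authenticated
    category: local
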