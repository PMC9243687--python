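# Indian national technical group consensus criteria, 2014. Classification
# requires at least one satisfied criterion in EACH of three sections —
# clinical findings, investigations, interventions — OR any single criterion
# signifying cardiorespiratory collapse.
#
# The full national indicator roster (>100 variables) is not reproduced
# here; this shipped default partitions the WHO severity indicators into the
# three sections (clinical findings = clinical flags, investigations =
# laboratory thresholds, interventions = management indicators) and defines
# the collapse shortcut as cardiac arrest, gasping, CPR, or non-anaesthetic
# intubation/ventilation. Facilities using the full national roster can
# supply their own YAML in the same grammar.
set_id: indian_2014
label: "Indian national criteria, 2014"
combinator: indian_sections
predicates:
  # section: clinical findings
  - {predicate_id: ind_clin_acute_cyanosis, category: clinical,
     indian_section: clinical_finding, expression: {flag: acute_cyanosis}}
  - {predicate_id: ind_clin_cardiac_arrest, category: clinical,
     indian_section: clinical_finding, expression: {flag: cardiac_arrest}}
  - {predicate_id: ind_clin_failure_to_form_clots, category: clinical,
     indian_section: clinical_finding, expression: {flag: failure_to_form_clots}}
  - {predicate_id: ind_clin_gasping, category: clinical,
     indian_section: clinical_finding, expression: {flag: gasping}}
  - predicate_id: ind_clin_jaundice_preeclampsia
    category: clinical
    indian_section: clinical_finding
    expression:
      any_of:
        - {flag: jaundice_with_preeclampsia}
        - {all_of: [{flag: jaundice}, {flag: preeclampsia}]}
  - {predicate_id: ind_clin_loss_of_consciousness, category: clinical,
     indian_section: clinical_finding, expression: {flag: loss_of_consciousness_gt_12h}}
  - {predicate_id: ind_clin_oliguria, category: clinical,
     indian_section: clinical_finding, expression: {flag: oliguria_nonresponsive}}
  - {predicate_id: ind_clin_resp_rate, category: clinical,
     indian_section: clinical_finding,
     expression: {measurement: respiratory_rate_per_min, outside: [6, 40]}}
  - {predicate_id: ind_clin_shock, category: clinical,
     indian_section: clinical_finding, expression: {flag: shock}}
  - {predicate_id: ind_clin_stroke, category: clinical,
     indian_section: clinical_finding, expression: {flag: stroke}}
  - {predicate_id: ind_clin_total_paralysis, category: clinical,
     indian_section: clinical_finding, expression: {flag: total_paralysis}}
  - predicate_id: ind_clin_uncontrollable_fits
    category: clinical
    indian_section: clinical_finding
    expression:
      any_of: [{flag: uncontrollable_fits}, {flag: status_epilepticus}]
  # section: investigations
  - {predicate_id: ind_inv_bilirubin, category: laboratory,
     indian_section: investigation,
     expression: {measurement: bilirubin_mg_dL, cmp: ">", value: 6.0}}
  - {predicate_id: ind_inv_creatinine, category: laboratory,
     indian_section: investigation,
     expression: {measurement: creatinine_mg_dL, cmp: ">=", value: 3.5}}
  - {predicate_id: ind_inv_lactate, category: laboratory,
     indian_section: investigation,
     expression: {measurement: lactate_mmol_L, cmp: ">", value: 5}}
  - {predicate_id: ind_inv_pao2_fio2, category: laboratory,
     indian_section: investigation,
     expression: {measurement: pao2_fio2_mmHg, cmp: "<", value: 200}}
  - {predicate_id: ind_inv_ph, category: laboratory,
     indian_section: investigation,
     expression: {measurement: ph, cmp: "<", value: 7.1}}
  - {predicate_id: ind_inv_spo2, category: laboratory,
     indian_section: investigation,
     expression: {measurement: spo2_pct_sustained_60min, cmp: "<", value: 90}}
  - {predicate_id: ind_inv_thrombocytopenia, category: laboratory,
     indian_section: investigation,
     expression: {measurement: platelet_count_per_mm3, cmp: "<", value: 50000}}
  # section: interventions
  - {predicate_id: ind_int_cpr, category: management,
     indian_section: intervention, expression: {flag: cpr}}
  - {predicate_id: ind_int_dialysis, category: management,
     indian_section: intervention, expression: {flag: dialysis_acute_renal_failure}}
  - {predicate_id: ind_int_hysterectomy, category: management,
     indian_section: intervention, expression: {flag: hysterectomy}}
  - {predicate_id: ind_int_intubation, category: management,
     indian_section: intervention,
     expression: {flag: intubation_ventilation_gt_60min_non_anaesthetic}}
  - {predicate_id: ind_int_transfusion_ge5, category: management,
     indian_section: intervention,
     expression: {measurement: transfusion_units, cmp: ">=", value: 5}}
  - {predicate_id: ind_int_vasoactive, category: management,
     indian_section: intervention, expression: {flag: vasoactive_drug_use}}
  # section: cardiorespiratory collapse (any single criterion suffices)
  - {predicate_id: ind_collapse_cardiac_arrest, category: clinical,
     indian_section: collapse, expression: {flag: cardiac_arrest}}
  - {predicate_id: ind_collapse_cpr, category: management,
     indian_section: collapse, expression: {flag: cpr}}
  - {predicate_id: ind_collapse_gasping, category: clinical,
     indian_section: collapse, expression: {flag: gasping}}
  - {predicate_id: ind_collapse_intubation, category: management,
     indian_section: collapse,
     expression: {flag: intubation_ventilation_gt_60min_non_anaesthetic}}
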