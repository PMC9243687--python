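# WHO near-miss tool (2011): 25 severity indicators,
# 12 clinical / 7 laboratory / 6 management. A woman meeting any single
# indicator is classified with a severe maternal outcome (near miss if she
# survived).
set_id: who_2011
label: "WHO near-miss criteria, 2011"
combinator: any_one
predicates:
  # clinical (12)
  - {predicate_id: who_clin_acute_cyanosis, category: clinical,
     expression: {flag: acute_cyanosis}}
  - {predicate_id: who_clin_cardiac_arrest, category: clinical,
     expression: {flag: cardiac_arrest}}
  - {predicate_id: who_clin_failure_to_form_clots, category: clinical,
     expression: {flag: failure_to_form_clots}}
  - {predicate_id: who_clin_gasping, category: clinical,
     expression: {flag: gasping}}
  - predicate_id: who_clin_jaundice_preeclampsia
    category: clinical
    expression:
      any_of:
        - {flag: jaundice_with_preeclampsia}
        - {all_of: [{flag: jaundice}, {flag: preeclampsia}]}
  - {predicate_id: who_clin_loss_of_consciousness, category: clinical,
     expression: {flag: loss_of_consciousness_gt_12h}}
  - {predicate_id: who_clin_oliguria, category: clinical,
     expression: {flag: oliguria_nonresponsive}}
  - {predicate_id: who_clin_resp_rate, category: clinical,
     expression: {measurement: respiratory_rate_per_min, outside: [6, 40]}}
  - {predicate_id: who_clin_shock, category: clinical,
     expression: {flag: shock}}
  - {predicate_id: who_clin_stroke, category: clinical,
     expression: {flag: stroke}}
  - {predicate_id: who_clin_total_paralysis, category: clinical,
     expression: {flag: total_paralysis}}
  - predicate_id: who_clin_uncontrollable_fits
    category: clinical
    expression:
      any_of: [{flag: uncontrollable_fits}, {flag: status_epilepticus}]
  # laboratory (7)
  - {predicate_id: who_lab_bilirubin, category: laboratory,
     expression: {measurement: bilirubin_mg_dL, cmp: ">", value: 6.0}}
  - {predicate_id: who_lab_creatinine, category: laboratory,
     expression: {measurement: creatinine_mg_dL, cmp: ">=", value: 3.5}}
  - {predicate_id: who_lab_lactate, category: laboratory,
     expression: {measurement: lactate_mmol_L, cmp: ">", value: 5}}
  - {predicate_id: who_lab_pao2_fio2, category: laboratory,
     expression: {measurement: pao2_fio2_mmHg, cmp: "<", value: 200}}
  - {predicate_id: who_lab_ph, category: laboratory,
     expression: {measurement: ph, cmp: "<", value: 7.1}}
  - {predicate_id: who_lab_spo2, category: laboratory,
     expression: {measurement: spo2_pct_sustained_60min, cmp: "<", value: 90}}
  - {predicate_id: who_lab_thrombocytopenia, category: laboratory,
     expression: {measurement: platelet_count_per_mm3, cmp: "<", value: 50000}}
  # management (6)
  - {predicate_id: who_mgmt_cpr, category: management,
     expression: {flag: cpr}}
  - {predicate_id: who_mgmt_dialysis, category: management,
     expression: {flag: dialysis_acute_renal_failure}}
  - {predicate_id: who_mgmt_hysterectomy, category: management,
     expression: {flag: hysterectomy}}
  - {predicate_id: who_mgmt_intubation, category: management,
     expression: {flag: intubation_ventilation_gt_60min_non_anaesthetic}}
  - {predicate_id: who_mgmt_transfusion_ge5, category: management,
     expression: {measurement: transfusion_units, cmp: ">=", value: 5}}
  - {predicate_id: who_mgmt_vasoactive, category: management,
     expression: {flag: vasoactive_drug_use}}
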