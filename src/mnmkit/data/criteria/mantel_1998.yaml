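# Mantel et al. 1998: organ-dysfunction and management based criteria.
set_id: mantel_1998
label: "Mantel et al. criteria, 1998"
combinator: any_one
predicates:
  - {predicate_id: man_anaes_complication, category: clinical,
     expression: {flag: anaesthesia_complication}}
  - {predicate_id: man_cardio_cardiac_arrest, category: clinical,
     expression: {flag: cardiac_arrest}}
  - {predicate_id: man_cardio_pulmonary_oedema, category: clinical,
     expression: {flag: pulmonary_oedema}}
  - {predicate_id: man_haem_platelet_transfusion, category: management,
     expression: {flag: platelet_transfusion}}
  - {predicate_id: man_haem_transfusion_ge5, category: management,
     expression: {measurement: transfusion_units, cmp: ">=", value: 5}}
  - predicate_id: man_hepatic_jaundice_preeclampsia
    category: clinical
    expression:
      any_of:
        - {flag: jaundice_with_preeclampsia}
        - {all_of: [{flag: jaundice}, {flag: preeclampsia}]}
  - {predicate_id: man_immun_sepsis_icu, category: clinical,
     expression: {flag: sepsis_icu_admission}}
  - {predicate_id: man_metab_dka, category: clinical,
     expression: {flag: diabetic_ketoacidosis}}
  - {predicate_id: man_metab_thyroid_crisis, category: clinical,
     expression: {flag: thyroid_crisis}}
  - {predicate_id: man_neuro_coma_gt_12h, category: clinical,
     expression: {flag: loss_of_consciousness_gt_12h}}
  - {predicate_id: man_neuro_intracranial_haemorrhage, category: clinical,
     expression: {flag: intracranial_haemorrhage}}
  - {predicate_id: man_other_icu_admission, category: management,
     expression: {flag: icu_admission}}
  - {predicate_id: man_proc_hysterectomy, category: management,
     expression: {flag: hysterectomy}}
  - {predicate_id: man_renal_creatinine, category: laboratory,
     # > 400 umol/L, stored canonically as mg/dL (400 / 88.4)
     expression: {measurement: creatinine_mg_dL, cmp: ">", value: 4.52}}
  - {predicate_id: man_renal_oliguria, category: clinical,
     expression: {flag: oliguria_nonresponsive}}
  - {predicate_id: man_renal_urea, category: laboratory,
     expression: {measurement: urea_mmol_L, cmp: ">", value: 15}}
  - {predicate_id: man_resp_hypoxia, category: laboratory,
     expression: {measurement: spo2_pct_sustained_60min, cmp: "<", value: 90}}
  - {predicate_id: man_resp_intubation, category: management,
     expression: {flag: intubation_ventilation_gt_60min_non_anaesthetic}}
  - {predicate_id: man_resp_pao2_fio2, category: laboratory,
     expression: {measurement: pao2_fio2_mmHg, cmp: "<=", value: 300}}
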