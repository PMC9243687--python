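# Roberts et al. 2008 maternal morbidity outcome indicators. The original
# system is ICD-code based; each diagnosis/procedure code group is
# abstracted to a concept-level vocabulary flag.
set_id: roberts_2008
label: "Roberts et al. criteria, 2008"
combinator: any_one
predicates:
  - {predicate_id: rob_anaes_complication, category: clinical,
     expression: {flag: anaesthesia_complication}}
  - {predicate_id: rob_cardio_arrest_or_infarct, category: clinical,
     expression: {any_of: [{flag: cardiac_arrest}, {flag: myocardial_infarction}]}}
  - {predicate_id: rob_cardio_cardiac_failure, category: clinical,
     expression: {flag: cardiac_failure}}
  - {predicate_id: rob_cardio_shock, category: clinical,
     expression: {flag: shock}}
  - {predicate_id: rob_haem_any_transfusion, category: management,
     expression: {measurement: transfusion_units, cmp: ">=", value: 1}}
  - {predicate_id: rob_haem_dic, category: clinical, expression: {flag: dic}}
  - {predicate_id: rob_haem_sickle_cell_crisis, category: clinical,
     expression: {flag: sickle_cell_crisis}}
  - {predicate_id: rob_neuro_cerebral_oedema_coma, category: clinical,
     expression: {flag: cerebral_oedema_or_coma}}
  - {predicate_id: rob_neuro_cva, category: clinical,
     expression: {flag: cerebrovascular_accident}}
  - {predicate_id: rob_neuro_status_epilepticus, category: clinical,
     expression: {flag: status_epilepticus}}
  - {predicate_id: rob_other_acute_abdomen, category: clinical,
     expression: {flag: acute_abdomen}}
  - {predicate_id: rob_other_acute_appendicitis, category: clinical,
     expression: {flag: acute_appendicitis}}
  - {predicate_id: rob_other_acute_psychosis, category: clinical,
     expression: {flag: acute_psychosis}}
  - {predicate_id: rob_proc_bleeding_control, category: management,
     expression: {flag: surgical_intervention_for_bleeding}}
  - {predicate_id: rob_proc_hysterectomy, category: management,
     expression: {flag: hysterectomy}}
  - {predicate_id: rob_proc_laparotomy_other, category: management,
     expression: {flag: laparotomy_other}}
  - {predicate_id: rob_proc_uterine_rupture, category: management,
     expression: {any_of: [{flag: ruptured_uterus}, {flag: uterine_rupture_repair}]}}
  - {predicate_id: rob_renal_arf, category: clinical,
     expression: {flag: acute_renal_failure}}
  - {predicate_id: rob_renal_dialysis, category: management,
     expression: {flag: dialysis_acute_renal_failure}}
  - {predicate_id: rob_resp_asthma, category: clinical,
     expression: {flag: acute_severe_asthma}}
  - {predicate_id: rob_resp_obstetric_embolism, category: clinical,
     expression: {flag: obstetric_embolism}}
  - predicate_id: rob_resp_ventilation
    category: management
    expression:
      any_of:
        - {flag: intubation_ventilation_gt_60min_non_anaesthetic}
        - {flag: tracheostomy}
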