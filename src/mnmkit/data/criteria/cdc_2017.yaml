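# CDC severe maternal morbidity indicators, 2017. ICD-code based in the
# original; each code group is abstracted to a concept-level flag.
set_id: cdc_2017
label: "CDC criteria, 2017"
combinator: any_one
predicates:
  - {predicate_id: cdc_anaesthesia_complication, category: clinical,
     expression: {flag: anaesthesia_complication}}
  - {predicate_id: cdc_ards, category: clinical, expression: {flag: ards}}
  - {predicate_id: cdc_amniotic_fluid_embolism, category: clinical,
     expression: {flag: amniotic_fluid_embolism}}
  - {predicate_id: cdc_cardiac_arrest, category: clinical,
     expression: {flag: cardiac_arrest}}
  - {predicate_id: cdc_cerebrovascular, category: clinical,
     expression: {flag: cerebrovascular_accident}}
  - {predicate_id: cdc_dic, category: clinical, expression: {flag: dic}}
  - {predicate_id: cdc_eclampsia, category: clinical, expression: {flag: eclampsia}}
  - {predicate_id: cdc_embolism, category: clinical,
     expression: {flag: obstetric_embolism}}
  - {predicate_id: cdc_hysterectomy, category: management,
     expression: {flag: hysterectomy}}
  - {predicate_id: cdc_myocardial_infarction, category: clinical,
     expression: {flag: myocardial_infarction}}
  - {predicate_id: cdc_pulmonary_oedema_heart_failure, category: clinical,
     expression: {any_of: [{flag: pulmonary_oedema}, {flag: cardiac_failure}]}}
  - {predicate_id: cdc_renal_failure, category: clinical,
     expression: {flag: acute_renal_failure}}
  - {predicate_id: cdc_rhythm_conversion, category: management,
     expression: {flag: cardiac_rhythm_conversion}}
  - {predicate_id: cdc_sepsis, category: clinical,
     expression: {any_of: [{flag: severe_sepsis}, {flag: sepsis_icu_admission}]}}
  - {predicate_id: cdc_shock, category: clinical, expression: {flag: shock}}
  - {predicate_id: cdc_sickle_cell_crisis, category: clinical,
     expression: {flag: sickle_cell_crisis}}
  - {predicate_id: cdc_tracheostomy, category: management,
     expression: {flag: tracheostomy}}
  - {predicate_id: cdc_transfusion_any, category: management,
     expression: {measurement: transfusion_units, cmp: ">=", value: 1}}
  - predicate_id: cdc_ventilation
    category: management
    expression:
      any_of:
        - {flag: intubation_ventilation_gt_60min_non_anaesthetic}
        - {flag: tracheostomy}
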