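# WHO potentially-life-threatening-condition (PLTC) screen: the inclusion
# tier upstream of near-miss classification. Thresholds here are screening
# thresholds, deliberately looser than the near-miss ones (platelets
# < 100 000/mm3 here vs < 50 000 in the WHO near-miss tool).
set_id: pltc_screen
label: "WHO potentially life-threatening condition screen"
combinator: any_one
predicates:
  # haemorrhagic disorders
  - {predicate_id: pltc_ectopic_pregnancy, category: clinical,
     pltc_category: haemorrhagic, expression: {flag: ectopic_pregnancy}}
  - {predicate_id: pltc_placenta_praevia, category: clinical,
     pltc_category: haemorrhagic, expression: {flag: placenta_praevia}}
  - {predicate_id: pltc_placental_abruption, category: clinical,
     pltc_category: haemorrhagic, expression: {flag: placental_abruption}}
  - {predicate_id: pltc_postpartum_haemorrhage, category: clinical,
     pltc_category: haemorrhagic, expression: {flag: postpartum_haemorrhage}}
  - {predicate_id: pltc_ruptured_uterus, category: clinical,
     pltc_category: haemorrhagic, expression: {flag: ruptured_uterus}}
  - {predicate_id: pltc_severe_bleeding, category: clinical,
     pltc_category: haemorrhagic, expression: {flag: severe_bleeding}}
  # hypertensive disorders
  - {predicate_id: pltc_eclampsia, category: clinical,
     pltc_category: hypertensive, expression: {flag: eclampsia}}
  - {predicate_id: pltc_hellp, category: clinical,
     pltc_category: hypertensive, expression: {flag: hellp}}
  - {predicate_id: pltc_hypertensive_urgency, category: clinical,
     pltc_category: hypertensive, expression: {flag: hypertensive_urgency}}
  - {predicate_id: pltc_severe_preeclampsia, category: clinical,
     pltc_category: hypertensive, expression: {flag: severe_preeclampsia}}
  # other systemic disorders
  - {predicate_id: pltc_pulmonary_oedema, category: clinical,
     pltc_category: systemic, expression: {flag: pulmonary_oedema}}
  - predicate_id: pltc_seizures
    category: clinical
    pltc_category: systemic
    expression:
      any_of:
        - {flag: seizures}
        - {flag: status_epilepticus}
        - {flag: uncontrollable_fits}
  - predicate_id: pltc_sepsis
    category: clinical
    pltc_category: systemic
    expression:
      any_of:
        - {flag: sepsis}
        - {flag: severe_sepsis}
        - {flag: sepsis_icu_admission}
  - {predicate_id: pltc_shock, category: clinical,
     pltc_category: systemic, expression: {flag: shock}}
  - {predicate_id: pltc_thrombocytopenia, category: laboratory,
     pltc_category: systemic,
     expression: {measurement: platelet_count_per_mm3, cmp: "<", value: 100000}}
  - {predicate_id: pltc_thyroid_crisis, category: clinical,
     pltc_category: systemic, expression: {flag: thyroid_crisis}}
  # severity-indicating management
  - {predicate_id: pltc_central_venous_access, category: management,
     pltc_category: management, expression: {flag: central_venous_access}}
  - {predicate_id: pltc_hysterectomy, category: management,
     pltc_category: management, expression: {flag: hysterectomy}}
  - {predicate_id: pltc_surgical_bleeding_control, category: management,
     pltc_category: management,
     expression: {flag: surgical_intervention_for_bleeding}}
  - {predicate_id: pltc_transfusion_any, category: management,
     pltc_category: management,
     expression: {measurement: transfusion_units, cmp: ">=", value: 1}}
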