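# Global Network Near-Miss Maternal Mortality System (Chou et al. 2016):
# the WHO tool with laboratory indicators removed (for settings where labs
# are not uniformly available), blood transfusion of ANY volume, and
# eclampsia added.
set_id: global_network_2016
label: "Global Network criteria, 2016"
combinator: any_one
predicates:
  - {predicate_id: gn_cardio_cardiac_arrest, category: clinical,
     expression: {flag: cardiac_arrest}}
  - {predicate_id: gn_cardio_cpr, category: management, expression: {flag: cpr}}
  - {predicate_id: gn_cardio_shock, category: clinical, expression: {flag: shock}}
  - {predicate_id: gn_cardio_vasoactive, category: management,
     expression: {flag: vasoactive_drug_use}}
  - {predicate_id: gn_haem_any_transfusion, category: management,
     expression: {measurement: transfusion_units, cmp: ">=", value: 1}}
  - {predicate_id: gn_haem_failure_to_form_clots, category: clinical,
     expression: {flag: failure_to_form_clots}}
  - {predicate_id: gn_hepatic_eclampsia, category: clinical,
     expression: {flag: eclampsia}}
  - predicate_id: gn_hepatic_jaundice_preeclampsia
    category: clinical
    expression:
      any_of:
        - {flag: jaundice_with_preeclampsia}
        - {all_of: [{flag: jaundice}, {flag: preeclampsia}]}
  - {predicate_id: gn_neuro_loss_of_consciousness, category: clinical,
     expression: {flag: loss_of_consciousness_gt_12h}}
  - {predicate_id: gn_neuro_paralysis, category: clinical,
     expression: {flag: total_paralysis}}
  - {predicate_id: gn_neuro_stroke, category: clinical, expression: {flag: stroke}}
  - predicate_id: gn_neuro_uncontrollable_fits
    category: clinical
    expression:
      any_of: [{flag: uncontrollable_fits}, {flag: status_epilepticus}]
  - {predicate_id: gn_proc_bleeding_surgery, category: management,
     expression: {flag: surgical_intervention_for_bleeding}}
  - {predicate_id: gn_renal_dialysis, category: management,
     expression: {flag: dialysis_acute_renal_failure}}
  - {predicate_id: gn_renal_oliguria, category: clinical,
     expression: {flag: oliguria_nonresponsive}}
  - {predicate_id: gn_resp_acute_cyanosis, category: clinical,
     expression: {flag: acute_cyanosis}}
  - {predicate_id: gn_resp_gasping, category: clinical, expression: {flag: gasping}}
  - {predicate_id: gn_resp_intubation, category: management,
     expression: {flag: intubation_ventilation_gt_60min_non_anaesthetic}}
  - {predicate_id: gn_resp_rate, category: clinical,
     expression: {measurement: respiratory_rate_per_min, outside: [6, 40]}}
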