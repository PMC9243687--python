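# Waterstone et al. 2001: clinical-diagnosis based criteria.
set_id: waterstone_2001
label: "Waterstone et al. criteria, 2001"
combinator: any_one
predicates:
  - {predicate_id: wat_eclampsia, category: clinical, expression: {flag: eclampsia}}
  - {predicate_id: wat_hellp, category: clinical, expression: {flag: hellp}}
  - {predicate_id: wat_ruptured_uterus, category: clinical,
     expression: {flag: ruptured_uterus}}
  - {predicate_id: wat_severe_bleeding, category: clinical,
     expression: {flag: severe_bleeding}}
  - {predicate_id: wat_severe_preeclampsia, category: clinical,
     expression: {flag: severe_preeclampsia}}
  - {predicate_id: wat_severe_sepsis, category: clinical,
     expression: {flag: severe_sepsis}}
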