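# Controlled vocabulary of maternal near-miss indicator tokens.
# kind: condition_flag | management_flag | measurement
# measurement tokens carry a unit; flag tokens carry none.
version: "1.0"
tokens:
  # ---- clinical condition flags -------------------------------------------
  - {name: acute_cyanosis, kind: condition_flag, label: "Acute cyanosis"}
  - {name: gasping, kind: condition_flag, label: "Gasping"}
  - {name: cardiac_arrest, kind: condition_flag, label: "Cardiac arrest"}
  - {name: stroke, kind: condition_flag, label: "Stroke"}
  - {name: shock, kind: condition_flag, label: "Shock"}
  - {name: uncontrollable_fits, kind: condition_flag, label: "Uncontrollable fits"}
  - {name: total_paralysis, kind: condition_flag, label: "Total paralysis"}
  - {name: loss_of_consciousness_gt_12h, kind: condition_flag,
     label: "Loss of consciousness or coma lasting > 12 hours"}
  - {name: jaundice_with_preeclampsia, kind: condition_flag,
     label: "Jaundice in the presence of pre-eclampsia (composite flag)"}
  - {name: jaundice, kind: condition_flag, label: "Jaundice"}
  - {name: preeclampsia, kind: condition_flag, label: "Pre-eclampsia (any severity)"}
  - {name: failure_to_form_clots, kind: condition_flag, label: "Failure to form clots"}
  - {name: oliguria_nonresponsive, kind: condition_flag,
     label: "Oliguria non-responsive to fluids or diuretics"}
  - {name: pulmonary_oedema, kind: condition_flag, label: "Pulmonary oedema"}
  - {name: eclampsia, kind: condition_flag, label: "Eclampsia"}
  - {name: severe_preeclampsia, kind: condition_flag, label: "Severe pre-eclampsia"}
  - {name: hellp, kind: condition_flag, label: "HELLP syndrome"}
  - {name: severe_sepsis, kind: condition_flag, label: "Severe sepsis"}
  - {name: sepsis, kind: condition_flag, label: "Sepsis (not requiring ICU admission)"}
  - {name: sepsis_icu_admission, kind: condition_flag,
     label: "Sepsis leading to intensive care admission"}
  - {name: severe_bleeding, kind: condition_flag, label: "Severe obstetric bleeding"}
  - {name: ruptured_uterus, kind: condition_flag, label: "Ruptured uterus"}
  - {name: diabetic_ketoacidosis, kind: condition_flag, label: "Diabetic ketoacidosis"}
  - {name: thyroid_crisis, kind: condition_flag, label: "Thyroid crisis"}
  - {name: dic, kind: condition_flag, label: "Disseminated intravascular coagulation"}
  - {name: sickle_cell_crisis, kind: condition_flag, label: "Sickle cell disease with crisis"}
  - {name: status_epilepticus, kind: condition_flag, label: "Status epilepticus"}
  - {name: cerebrovascular_accident, kind: condition_flag, label: "Cerebrovascular accident"}
  - {name: cerebral_oedema_or_coma, kind: condition_flag, label: "Cerebral oedema or coma"}
  - {name: intracranial_haemorrhage, kind: condition_flag,
     label: "Subarachnoid or intracerebral haemorrhage"}
  - {name: acute_renal_failure, kind: condition_flag, label: "Acute renal failure"}
  - {name: cardiac_failure, kind: condition_flag, label: "Cardiac (heart) failure"}
  - {name: myocardial_infarction, kind: condition_flag,
     label: "Acute myocardial infarction or aneurysm"}
  - {name: obstetric_embolism, kind: condition_flag,
     label: "Obstetric embolism (air, thrombotic)"}
  - {name: acute_severe_asthma, kind: condition_flag, label: "Acute severe asthma"}
  - {name: ards, kind: condition_flag, label: "Adult respiratory distress syndrome"}
  - {name: amniotic_fluid_embolism, kind: condition_flag, label: "Amniotic fluid embolism"}
  - {name: anaesthesia_complication, kind: condition_flag,
     label: "Major anaesthesia complication"}
  - {name: acute_abdomen, kind: condition_flag, label: "Acute abdomen"}
  - {name: acute_psychosis, kind: condition_flag, label: "Acute psychosis"}
  - {name: acute_appendicitis, kind: condition_flag, label: "Acute appendicitis"}
  - {name: eclampsia_jaundice_context, kind: condition_flag,
     label: "Eclampsia arising in a jaundice context (composite flag)"}
  # screening-tier / context flags (potentially life-threatening conditions,
  # sociodemographic-free generator covariates)
  - {name: placental_abruption, kind: condition_flag, label: "Placental abruption"}
  - {name: placenta_praevia, kind: condition_flag, label: "Placenta praevia"}
  - {name: postpartum_haemorrhage, kind: condition_flag, label: "Postpartum haemorrhage"}
  - {name: ectopic_pregnancy, kind: condition_flag, label: "Ectopic pregnancy"}
  - {name: hypertensive_urgency, kind: condition_flag, label: "Hypertensive urgency"}
  - {name: seizures, kind: condition_flag, label: "Seizures (not status epilepticus)"}
  - {name: anaemia, kind: condition_flag, label: "Moderate to severe anaemia"}
  - {name: diabetes, kind: condition_flag, label: "Diabetes in pregnancy"}
  - {name: cardiac_disease, kind: condition_flag, label: "Heart disease (compensated)"}
  - {name: obstructed_labour, kind: condition_flag, label: "Prolonged or obstructed labour"}
  # ---- management flags ----------------------------------------------------
  - {name: vasoactive_drug_use, kind: management_flag,
     label: "Use of continuous vasoactive drugs"}
  - {name: intubation_ventilation_gt_60min_non_anaesthetic, kind: management_flag,
     label: "Intubation and ventilation > 60 min not related to anaesthesia"}
  - {name: hysterectomy, kind: management_flag,
     label: "Hysterectomy following infection or haemorrhage"}
  - {name: dialysis_acute_renal_failure, kind: management_flag,
     label: "Dialysis for acute renal failure"}
  - {name: cpr, kind: management_flag, label: "Cardiopulmonary resuscitation"}
  - {name: icu_admission, kind: management_flag,
     label: "Intensive care unit admission for any reason"}
  - {name: surgical_intervention_for_bleeding, kind: management_flag,
     label: "Surgical procedure to stop bleeding"}
  - {name: uterine_rupture_repair, kind: management_flag,
     label: "Repair of ruptured or inverted uterus"}
  - {name: laparotomy_other, kind: management_flag,
     label: "Other laparotomy / re-exploration (reclosure, haematoma evacuation, visceral repair)"}
  - {name: tracheostomy, kind: management_flag, label: "Temporary tracheostomy"}
  - {name: cardiac_rhythm_conversion, kind: management_flag,
     label: "Conversion of cardiac rhythm"}
  - {name: platelet_transfusion, kind: management_flag,
     label: "Platelet transfusion for acute thrombocytopenia"}
  - {name: central_venous_access, kind: management_flag, label: "Central venous access"}
  # ---- measurements ---------------------------------------------------------
  - {name: ph, kind: measurement, unit: "pH", label: "Arterial pH"}
  - {name: lactate_mmol_L, kind: measurement, unit: "mmol/L", label: "Lactate"}
  - {name: creatinine_mg_dL, kind: measurement, unit: "mg/dL", label: "Serum creatinine"}
  - {name: bilirubin_mg_dL, kind: measurement, unit: "mg/dL", label: "Total bilirubin"}
  - {name: platelet_count_per_mm3, kind: measurement, unit: "/mm3", label: "Platelet count"}
  - {name: spo2_pct_sustained_60min, kind: measurement, unit: "%",
     label: "Oxygen saturation sustained for >= 60 min"}
  - {name: pao2_fio2_mmHg, kind: measurement, unit: "mmHg", label: "PaO2/FiO2 ratio"}
  - {name: respiratory_rate_per_min, kind: measurement, unit: "/min", label: "Respiratory rate"}
  - {name: urine_output_mL_24h, kind: measurement, unit: "mL/24h", label: "Urine output in 24 h"}
  - {name: urea_mmol_L, kind: measurement, unit: "mmol/L", label: "Serum urea"}
  - {name: transfusion_units, kind: measurement, unit: "units",
     label: "Units of whole blood or packed red cells transfused"}
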