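# mnmkit — maternal near-miss surveillance toolkit

A maternal **near miss** is a woman who nearly died but survived a
complication of pregnancy, childbirth, or the 42 days after its end.
Because near misses are far more frequent than maternal deaths and share
their causal pathways, facilities audit them to measure obstetric quality
of care. The difficulty is that no single case definition is in universal
use: the WHO near-miss tool (2011) relies on clinical, laboratory and
management severity indicators; the Global Network system (2016) drops the
laboratory criteria for low-resource settings and counts any blood
transfusion; Mantel (1998) and Waterstone (2001) use organ dysfunction and
clinical diagnoses; Roberts (2008) and the CDC (2017) indicators are
ICD-code based; and the Indian national consensus criteria (2014) require
one satisfied criterion in each of three sections (clinical findings,
investigations, interventions) or a single cardiorespiratory-collapse
criterion. Counts, and the quality indices derived from them, differ
materially depending on which definition a facility applies.

`mnmkit` makes those definitions executable and comparable. It provides:

- a **controlled vocabulary** of indicator tokens (condition flags,
  management flags, measurements with declared units) and a validated
  patient-record/cohort model;
- a **declarative criteria engine**: all seven criteria sets (plus the WHO
  potentially-life-threatening-condition screen) shipped as YAML predicate
  documents, evaluated with per-record provenance of every matched
  predicate. A missing laboratory value never asserts severity;
- the **WHO process indicators**, for live births LB, near misses MNM and
  criteria-identified deaths MD:

  - maternal near-miss ratio: `MNM / LB × 1000`
  - severe maternal outcome ratio: `(MNM + MD) / LB × 1000`
  - mortality index: `MD / (MNM + MD) × 100` (lower is better care)
  - MNM:MD ratio: `MNM / MD` (higher is better care)

  plus maternal mortality ratio per 100 000 live births, screening-tier
  incidence, and per-condition case-fatality tables;
- a **transfusion-threshold sensitivity analysis**: near-miss counts
  bucketed by units of blood transfused, and a sweep of the transfusion
  cut-off (the WHO tool requires ≥ 5 units; several other sets count any
  volume, which inflates counts wherever anaemia is a common transfusion
  indication);
- a **synthetic cohort generator** that reproduces the marginal structure
  of a screened referral-hospital population (condition prevalences,
  severity-indicator frequencies among severe outcomes, a nested death
  fraction, a transfusion-unit distribution), so the whole pipeline is
  testable without patient data.

## Worked example

Generate a study-sized synthetic cohort (1833 screened women, 37 590
live births) and report the WHO indicators:

```
$ mnmkit simulate --seed 42 --out cohort.csv
wrote cohort.csv (1833 records, 37590 live births)

$ mnmkit report cohort.csv --live-births 37590 -c who_2011
{
  "set_id": "who_2011",
  "n_near_miss": 326,
  "n_deaths_identified": 53,
  "n_deaths_missed": 0,
  "n_smo": 379,
  ...
  "rounded": {
    "mnm_ratio_per_1000": 8.7,
    "smo_ratio_per_1000": 10.1,
    "mortality_index_pct": 14.0,
    "mnm_to_md_ratio": 6.15
  }
}
```

379 of the 1833 screened women met a WHO severity indicator (326 near
misses and 53 deaths, none missed), giving a near-miss ratio of 8.7 per
1000 live births and a mortality index of 14.0%. Comparing all seven
criteria sets over the identical cohort:

```
$ mnmkit compare cohort.csv --live-births 37590 --out comparison
$ cat comparison.csv
set_id,n_smo,n_near_miss,n_deaths_identified,n_deaths_missed,smo_ratio_per_1000,mnm_ratio_per_1000,mortality_index_pct,mnm_to_md_ratio
cdc_2017,571,537,34,19,15.2,14.3,6.0,15.79
global_network_2016,613,560,53,0,16.3,14.9,8.6,10.57
indian_2014,127,108,19,34,3.4,2.9,15.0,5.68
mantel_1998,267,230,37,16,7.1,6.1,13.9,6.22
roberts_2008,501,467,34,19,13.3,12.4,6.8,13.74
waterstone_2001,307,295,12,41,8.2,7.8,3.9,24.58
who_2011,379,326,53,0,10.1,8.7,14.0,6.15
```

The pattern is the methodological point: the any-volume-transfusion sets
(Global Network, CDC, Roberts) identify many more "near misses" than the
WHO tool on the same women; the narrower clinical sets (Waterstone,
Mantel) and the three-section Indian rule identify fewer and fail to flag
women who died (`n_deaths_missed`); only the WHO and Global Network
criteria catch every death. Other verbs: `mnmkit list-criteria`,
`validate`, `classify` (per-record verdicts with matched-predicate
provenance), `curve` (near miss by units transfused), and `run` (full
pipeline from a YAML config). Custom criteria sets can be supplied as YAML
in the same predicate grammar as the shipped ones
(`src/mnmkit/data/criteria/`).

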