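# Methods

## Classification model

Every criteria set is compiled to the same declarative form: a list of
predicates over a controlled vocabulary of indicator tokens, plus a
combination rule. A predicate is one of

- `flag_present(token)` — a clinician-asserted condition or a management
  event (e.g. `shock`, `cpr`);
- `threshold(measurement, cmp, value)` — a comparison against a numeric
  measurement in its declared unit (e.g. platelets `< 50 000 /mm³`);
- `range_out(measurement, low, high)` — true outside the open interval
  (used for respiratory rate `> 40 or < 6 /min`);
- `all_of` / `any_of` compounds.

Two combination rules exist. `any_one` (used by six sets and the
screening tier): positive iff at least one predicate is satisfied.
`indian_sections` (Indian national criteria): positive iff at least one
predicate is satisfied in *each* of the sections clinical findings,
investigations and interventions, or any single predicate in the
cardiorespiratory-collapse section is satisfied.

A classification result records every satisfied predicate
(lexicographically sorted, so outputs are byte-stable) and a verdict
crossing positivity with the vital outcome: `near_miss` (positive,
survived), `maternal_death_identified` (positive, died),
`maternal_death_missed` (negative, died), `negative`. Missed deaths are
the key comparative statistic between criteria sets: a definition that
fails to flag a woman who subsequently died is under-detecting severity.

### Assumptions and conventions

- **Missingness.** An absent measurement fails every threshold and range
  predicate. A laboratory value that was never taken cannot assert
  severity; this is also what makes the clinically based sets usable
  where laboratory services are unavailable. An absent value is distinct
  from any numeric value (0.0 is a value, not missing). The transfusion
  unit count is the one exception: it is always defined, with 0 meaning
  none recorded.
- **Units.** Measurements are stored in a single canonical unit per
  token; dual-unit thresholds (creatinine, bilirubin quoted in both
  µmol/L and mg/dL) are stored in mg/dL, and a µmol/L → mg/dL conversion
  (creatinine ÷ 88.4, bilirubin ÷ 17.1) is applied at CSV ingest when a
  units directive declares the column. Keeping one canonical unit avoids
  the drift that arises when the two printed thresholds are not exact
  conversions of each other (300 µmol/L is 3.39 mg/dL, not 3.5).
- **Thresholds at the boundary.** The WHO transfusion criterion is ≥ 5
  units (five or more); severe thrombocytopenia is strictly < 50 000/mm³;
  the screening-tier threshold is the looser < 100 000/mm³. Respiratory
  rate uses the open interval (6, 40): exactly 6 or 40 is negative.
- **ICD-based sets.** The Roberts and CDC systems are defined over ICD
  code groups; this package abstracts each code group to a concept-level
  vocabulary flag (e.g. "acute renal failure" → `acute_renal_failure`).
  Mapping raw ICD-coded charts onto those flags is an ingest concern,
  outside the engine.
- **Composite indicators.** "Jaundice in the presence of pre-eclampsia"
  is accepted through either route: a single composite flag set by the
  data provider, or the conjunction of `jaundice` and `preeclampsia`
  flags; the compound route is preferred.
- **Indian roster.** The full national indicator roster (over a hundred
  variables) is not public in a tabulated form; the shipped default
  partitions the WHO severity indicators into the three sections
  (clinical findings = clinical flags, investigations = laboratory
  thresholds, interventions = management indicators), with collapse =
  {cardiac arrest, gasping, CPR, non-anaesthetic intubation/ventilation}.
  The combination rule is the contribution being modelled; the roster is
  user-overridable YAML.

## Process indicators

For a criteria set applied to one cohort with live-birth denominator LB:
near-miss ratio `MNM/LB × 1000`, severe-maternal-outcome ratio
`(MNM+MD)/LB × 1000`, mortality index `MD/(MNM+MD) × 100`, and MNM:MD
ratio `MNM/MD`. Only deaths the set itself identifies enter MD; missed
deaths are reported alongside, and identified + missed always equals the
cohort's total deaths. With no identified deaths the MNM:MD ratio is a
tagged undefined value, serialized as `null`, never infinity; with an
empty cohort the mortality index is reported as 0. The live-birth
denominator is an explicit parameter everywhere — in a screened cohort it
exceeds the number of records by an order of magnitude and must never be
inferred from the row count.

All values are carried at full precision; presentation rounding
(half-away-from-zero, 1 decimal for ratios and the index, 2 for MNM:MD)
is provided alongside, never instead. Published tables of this kind mix
rounding and truncation, so only cells consistent with standard rounding
of their own counts are used as test oracles.

## Transfusion analysis

`transfusion_curve` buckets transfused records by exact integer units
(1, …, k−1, ≥ k; zero-unit records excluded; fractional units are
rejected at ingest) and counts the women each criteria set identifies per
bucket. `threshold_sweep` replaces the single transfusion threshold
predicate of a base set with ≥ t for each t in a list and counts
near-miss verdicts (survivors). The two operations deliberately count
different things: the curve reports *women identified* per stratum (so
the ≥ 5-unit stratum is exactly saturated under the WHO set), the sweep
reports *near misses* (the quantity a facility would publish). Structural
guarantees: sweep counts are non-increasing in t; the sweep at t = 5
reproduces the base WHO classification; t = 1 is equivalent to an
any-volume criterion for integer units.

## Synthetic cohort generator

The generator emulates a screened referral-hospital population of
`n_records` women (default 1833) against `live_births` (default 37 590):

1. **Condition categories** (haemorrhage, infection, hypertensive,
   medical, labour-related) are independent Bernoulli draws at the
   published prevalences (0.112/0.055/0.567/0.644/0.009); categories
   overlap. Each category contributes one screening-tier context flag
   (e.g. hypertensive → hypertensive urgency, pre-eclampsia, severe
   pre-eclampsia, HELLP or eclampsia at fixed weights). Context flags are
   chosen from outside the WHO indicator list so that screened-but-not-
   severe women remain WHO-negative; a few of them are indicators of
   *other* sets, which is what makes those sets over- or under-call near
   miss relative to the WHO tool, as observed in real cohorts.
2. **Severe maternal outcome membership** is Bernoulli with
   `smo_fraction` (default 380/1833). SMO records draw WHO severity
   indicators as independent Bernoulli per token at the published
   marginal frequencies (e.g. ≥ 5-unit transfusion 108/380, severe
   thrombocytopenia 102/380); the published tables provide marginals
   only, so no joint structure is invented. Records drawing no indicator
   have one forced (proportionally to the frequencies); because forcing
   would inflate every marginal, the per-token draw probabilities are
   first calibrated by a small fixed-point iteration so the
   *post-forcing* marginals equal the targets exactly in expectation.
3. **Measurements** linked to drawn indicator tokens land uniformly in a
   clinically bounded severe range (platelets ~ U(5 000, 49 999) /mm³,
   creatinine ~ U(3.5, 8.0) mg/dL, …). A small consistency layer links
   flags to compatible measurements: a HELLP flag without a severe
   platelet draw receives a screening-level count U(50 000, 99 999).
   Measurements not implied by any drawn token are left missing, which
   mirrors practice (laboratories are ordered on indication) and
   exercises the missingness rule.
4. **Deaths** are drawn only among SMO records that carry at least one
   indicator in the WHO ∩ Global Network overlap (all non-laboratory WHO
   indicators except hysterectomy), at a per-record probability that
   preserves the overall `death_fraction` (default 57/1833) in
   expectation. Selecting rather than modifying records leaves the
   indicator marginals unbiased and guarantees zero missed deaths under
   both the WHO and Global Network criteria — the defining empirical
   property of those two sets. `atypical_death_fraction` (default 0)
   optionally adds deaths among non-SMO records to exercise missed-death
   counting.
5. **Transfusion volumes** follow a truncated geometric distribution
   (p = 0.45 on 1–10 units): records with the severe-transfusion token
   receive max(5, draw); other records are transfused 1–4 units with
   probability 0.17, calibrated so that roughly 407/1833 of records
   receive any transfusion — the any-volume inflation that motivates the
   threshold analysis. The event-timing mix approximates the published
   distribution (≈ 90% antenatal, dominated by the third trimester).

`recover_marginals` re-measures every spec probability on a generated
cohort and standardises the deviation by the binomial SD at the relevant
denominator, flagging |z| > 4.

### What the generator does and does not emulate

It reproduces marginal prevalences, indicator frequencies, nesting of
deaths, and the qualitative ordering of criteria sets. It does **not**
reproduce: real correlation structure among indicators (beyond the
documented consistency layer), per-criteria-set counts of the reference
study (those depend on unpublished joint structure), sociodemographics,
transfusion indication (anaemia vs haemorrhage), or longitudinal event
ordering. Passing tests therefore demonstrate correctness of the
classification and indicator machinery under realistic marginals, not
fidelity of any joint distribution to a real hospital population.

## Numerical and design choices

- Presentation rounding is decimal half-away-from-zero, computed on the
  decimal representation (no binary-float tie surprises).
- Matched-predicate lists sort by predicate id; report collections sort
  by set id; CSV writers are byte-stable, so reruns with the same seed
  and config are byte-identical.
- Duplicate record ids, a non-positive live-birth denominator, invalid
  spec probabilities (including `death_fraction > smo_fraction`) and
  unknown tokens in criteria documents are rejected before any
  computation. Record-content problems are reported (field + token per
  violation), never thrown one at a time.
- Test problem sizes: engine/oracle equivalence on 10 000 random records
  across all eight predicate tables; marginal recovery at n = 50 000;
  study-scale checks at n = 1833. These sizes make the binomial
  tolerances meaningful while keeping the suite fast.
- The acceptance script reports closed-form indicator reproductions only
  for published cells that are arithmetically consistent with their own
  published counts under half-away-from-zero rounding; the handful of
  cells that are not (they appear to be truncated or internally
  inconsistent in the source table) are excluded rather than matched by
  ad-hoc rounding rules.

## Known limitations

- Concept-level abstraction of ICD-based sets means code-list nuances
  (e.g. Roberts' procedure-code granularity) are collapsed to flags.
- The shipped Indian roster is a WHO-indicator partition, not the full
  national list; facility-specific rosters should be supplied as YAML.
- "Shock" and similar clinical flags are clinician-asserted, with no
  blood-pressure cut-off; the engine does not second-guess them.
- No confidence intervals on indicators, no event sequencing, no
  severity grading beyond the binary verdicts.
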