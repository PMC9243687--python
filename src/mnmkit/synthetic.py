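"""Synthetic cohorts with the marginal structure of a referral-hospital
near-miss surveillance population.

The generator emulates a screened cohort of women with potentially
life-threatening conditions: overlapping condition categories drawn at
their published prevalences, a severe-maternal-outcome (SMO) subset whose
WHO severity-indicator frequencies match the published marginals, deaths
nested within the SMO subset, and a transfusion-unit distribution. Only
marginals are targeted — the source tables publish no correlation
structure — except for a small documented consistency layer (e.g. a HELLP
flag implies a compatible platelet count).

Two construction guarantees mirror the study's findings and are relied on
by tests: (i) with ``atypical_death_fraction = 0`` every death carries at
least one indicator in the WHO/Global Network overlap, so both of those
sets miss zero deaths; (ii) records outside the SMO subset never receive a
WHO severity indicator, so the WHO-positive count is binomial with mean
``n_records * smo_fraction``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .criteria import classify_cohort, load_builtin
from .model import Cohort, PatientRecord
from .vocabulary import CONDITION_CATEGORIES, default_vocabulary

# ---------------------------------------------------------------------------
# defaults: published marginals of the study population

#: Condition-category prevalences among 1833 women with potentially
#: life-threatening conditions (categories overlap; sums exceed 1).
DEFAULT_CONDITION_PREVALENCES = {
    "haemorrhage": 206 / 1833,
    "infection": 100 / 1833,
    "hypertensive": 1039 / 1833,
    "medical": 1181 / 1833,
    "labour_related": 17 / 1833,
}

#: WHO severity-indicator frequencies among 380 women with severe maternal
#: outcomes. Keys are vocabulary tokens; a drawn measurement token means
#: "this indicator is satisfied at WHO severity".
DEFAULT_INDICATOR_FREQS = {
    "acute_cyanosis": 0 / 380,
    "loss_of_consciousness_gt_12h": 14 / 380,
    "gasping": 1 / 380,
    "cardiac_arrest": 3 / 380,
    "respiratory_rate_per_min": 18 / 380,
    "stroke": 2 / 380,
    "shock": 31 / 380,
    "uncontrollable_fits": 19 / 380,
    "total_paralysis": 3 / 380,
    "oliguria_nonresponsive": 25 / 380,
    "jaundice_with_preeclampsia": 6 / 380,
    "failure_to_form_clots": 93 / 380,
    "spo2_pct_sustained_60min": 48 / 380,
    "ph": 14 / 380,
    "pao2_fio2_mmHg": 4 / 380,
    "lactate_mmol_L": 4 / 380,
    "creatinine_mg_dL": 24 / 380,
    "platelet_count_per_mm3": 102 / 380,
    "bilirubin_mg_dL": 26 / 380,
    "vasoactive_drug_use": 18 / 380,
    "intubation_ventilation_gt_60min_non_anaesthetic": 80 / 380,
    "hysterectomy": 35 / 380,
    "dialysis_acute_renal_failure": 19 / 380,
    "transfusion_units": 108 / 380,
    "cpr": 30 / 380,
}

#: WHO laboratory indicator tokens (the ones the Global Network set omits).
LAB_TOKENS = frozenset(
    {
        "spo2_pct_sustained_60min",
        "ph",
        "pao2_fio2_mmHg",
        "lactate_mmol_L",
        "creatinine_mg_dL",
        "platelet_count_per_mm3",
        "bilirubin_mg_dL",
    }
)

#: Tokens that satisfy both the WHO tool and the Global Network criteria.
#: Deaths are drawn only among records carrying one of these, which is what
#: guarantees zero missed deaths under either set. (Hysterectomy is WHO
#: management but has no Global Network counterpart, so it is excluded.)
DEATH_ELIGIBLE_TOKENS = frozenset(DEFAULT_INDICATOR_FREQS) - LAB_TOKENS - {"hysterectomy"}

#: Screening-tier context flags per condition category, drawn once per
#: category a record carries. These are deliberately outside the WHO
#: indicator list, so non-SMO records stay WHO-negative; a few are
#: indicators of OTHER criteria sets (eclampsia, severe pre-eclampsia,
#: severe sepsis, pulmonary oedema), which is what makes those sets
#: over-call near miss relative to the WHO tool, as observed in practice.
CONTEXT_FLAG_CHOICES = {
    "haemorrhage": (
        ("postpartum_haemorrhage", 0.45),
        ("placental_abruption", 0.30),
        ("ectopic_pregnancy", 0.15),
        ("placenta_praevia", 0.10),
    ),
    "hypertensive": (
        ("hypertensive_urgency", 0.47),
        ("preeclampsia", 0.28),
        ("severe_preeclampsia", 0.12),
        ("hellp", 0.08),
        ("eclampsia", 0.05),
    ),
    "infection": (
        ("sepsis", 0.75),
        ("severe_sepsis", 0.25),
    ),
    "medical": (
        ("anaemia", 0.37),
        ("diabetes", 0.27),
        ("cardiac_disease", 0.24),
        ("seizures", 0.08),
        ("pulmonary_oedema", 0.04),
    ),
    "labour_related": (("obstructed_labour", 1.0),),
}

#: Timing mix of the event (antenatal trimesters, intrapartum, postpartum,
#: post-abortion), roughly the study's distribution.
TIMING_CHOICES = (
    ("antenatal_t1", 0.03),
    ("antenatal_t2", 0.09),
    ("antenatal_t3", 0.78),
    ("intrapartum", 0.01),
    ("postpartum", 0.08),
    ("post_abortion", 0.01),
)

#: Draws that satisfy the WHO threshold for each measurement token, landing
#: uniformly in a clinically bounded severe range.
def _severe_draw(token: str, rng: np.random.Generator) -> float:
    if token == "spo2_pct_sustained_60min":
        return float(rng.uniform(60.0, 89.5))
    if token == "ph":
        return float(rng.uniform(6.80, 7.09))
    if token == "pao2_fio2_mmHg":
        return float(rng.uniform(80.0, 199.0))
    if token == "lactate_mmol_L":
        return float(rng.uniform(5.1, 15.0))
    if token == "creatinine_mg_dL":
        return float(rng.uniform(3.5, 8.0))
    if token == "platelet_count_per_mm3":
        return float(rng.integers(5_000, 50_000))
    if token == "bilirubin_mg_dL":
        return float(rng.uniform(6.1, 20.0))
    if token == "respiratory_rate_per_min":
        return float(rng.integers(41, 61)) if rng.random() < 0.5 else float(rng.integers(1, 6))
    raise KeyError(token)


@dataclass
class CohortSpec:
    """Generator parameters; defaults are the study population's marginals.

    ``death_fraction`` is the overall death probability per record (deaths
    are nested within the SMO subset, so it must not exceed
    ``smo_fraction``). ``atypical_death_fraction`` is a per-record death
    probability among non-SMO records carrying no WHO indicator; it is 0 by
    default and exists to exercise missed-death counting in other criteria
    sets. ``nonsevere_transfusion_prob`` is the probability that a record
    without the severe (>= 5 units) transfusion indicator is transfused
    1-4 units, calibrated so that roughly 407/1833 of records receive any
    transfusion.
    """

    n_records: int = 1833
    live_births: int = 37_590
    death_fraction: float = 57 / 1833
    smo_fraction: float = 380 / 1833
    condition_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PREVALENCES)
    )
    indicator_freqs_among_smo: dict = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_FREQS)
    )
    transfusion_unit_distribution: dict = field(
        default_factory=lambda: {"p": 0.45, "min": 1, "max": 10}
    )
    nonsevere_transfusion_prob: float = 0.17
    atypical_death_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")
        if self.live_births < 1:
            raise ValueError("live_births must be >= 1")
        probs = {
            "death_fraction": self.death_fraction,
            "smo_fraction": self.smo_fraction,
            "atypical_death_fraction": self.atypical_death_fraction,
            "nonsevere_transfusion_prob": self.nonsevere_transfusion_prob,
            **{f"prevalence[{k}]": v for k, v in self.condition_prevalences.items()},
            **{f"indicator[{k}]": v for k, v in self.indicator_freqs_among_smo.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if self.death_fraction > self.smo_fraction:
            raise ValueError("death_fraction must not exceed smo_fraction")
        unknown = set(self.condition_prevalences) - set(CONDITION_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown condition categories: {sorted(unknown)}")
        vocab = default_vocabulary()
        unknown = {t for t in self.indicator_freqs_among_smo if t not in vocab}
        if unknown:
            raise ValueError(f"unknown indicator tokens: {sorted(unknown)}")
        if self.smo_fraction > 0 and not any(self.indicator_freqs_among_smo.values()):
            raise ValueError(
                "smo_fraction > 0 requires at least one positive indicator frequency"
            )
        dist = self.transfusion_unit_distribution
        if not (0.0 < dist["p"] <= 1.0 and 1 <= dist["min"] <= dist["max"]):
            raise ValueError("invalid transfusion_unit_distribution")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown CohortSpec fields: {sorted(unknown)}")
        return cls(**doc)


# ---------------------------------------------------------------------------
# sampling helpers


def _trunc_geom(rng: np.random.Generator, p: float, lo: int, hi: int) -> int:
    """Geometric-shaped draw truncated to the integer support [lo, hi]."""
    support = np.arange(lo, hi + 1)
    weights = (1.0 - p) ** (support - lo)
    return int(rng.choice(support, p=weights / weights.sum()))


def _weighted_choice(rng: np.random.Generator, choices) -> str:
    names = [c[0] for c in choices]
    weights = np.array([c[1] for c in choices], dtype=float)
    return str(rng.choice(names, p=weights / weights.sum()))


def _calibrate_token_probs(targets: np.ndarray, n_iter: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """Adjust per-token Bernoulli probabilities for the >= 1-token forcing.

    Tokens are drawn independently; records ending up with no token have
    one forced (chosen with probability proportional to the drawn
    frequencies). Forcing alone would inflate every marginal, so the draw
    probabilities are solved by fixed-point iteration such that the
    post-forcing marginal of token k is exactly ``targets[k]``:

        marginal_k = p_k + P0 * w_k,   P0 = prod(1 - p),  w_k = p_k / sum(p)

    Returns the calibrated draw probabilities and forcing weights.
    """
    p = targets.astype(float).copy()
    for _ in range(n_iter):
        p0 = float(np.prod(1.0 - p))
        s = p.sum()
        w = p / s if s > 0 else np.zeros_like(p)
        p = np.clip(targets - p0 * w, 0.0, 1.0)
    p0 = float(np.prod(1.0 - p))
    s = p.sum()
    w = p / s if s > 0 else np.zeros_like(p)
    return p, w


# ---------------------------------------------------------------------------
# generation


def generate(spec: CohortSpec) -> Cohort:
    """Generate a cohort; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    width = max(5, len(str(max(n, 1))))

    categories = sorted(spec.condition_prevalences)
    prev = np.array([spec.condition_prevalences[c] for c in categories])
    cat_matrix = rng.random((n, len(categories))) < prev

    smo_mask = rng.random(n) < spec.smo_fraction

    tokens = sorted(spec.indicator_freqs_among_smo)
    targets = np.array([spec.indicator_freqs_among_smo[t] for t in tokens])
    draw_p, force_w = _calibrate_token_probs(targets)
    token_matrix = rng.random((n, len(tokens))) < draw_p
    token_matrix[~smo_mask, :] = False
    # force at least one WHO indicator on SMO records that drew none
    for i in np.flatnonzero(smo_mask & ~token_matrix.any(axis=1)):
        token_matrix[i, rng.choice(len(tokens), p=force_w)] = True

    # deaths: only among SMO records carrying a WHO/Global Network-overlap
    # indicator, at a per-record probability that preserves the overall
    # death fraction in expectation
    eligible_cols = np.array([t in DEATH_ELIGIBLE_TOKENS for t in tokens])
    eligible = smo_mask & token_matrix[:, eligible_cols].any(axis=1)
    n_eligible = int(eligible.sum())
    died = np.zeros(n, dtype=bool)
    if n_eligible > 0 and spec.death_fraction > 0:
        p_die = min(1.0, spec.death_fraction * n / n_eligible)
        died[eligible] = rng.random(n_eligible) < p_die
    if spec.atypical_death_fraction > 0:
        atypical = ~smo_mask & (rng.random(n) < spec.atypical_death_fraction)
        died |= atypical

    dist = spec.transfusion_unit_distribution
    token_index = {t: j for j, t in enumerate(tokens)}
    records = []
    for i in range(n):
        flags: set[str] = set()
        measurements: dict[str, float] = {}
        units = 0
        record_cats = frozenset(c for j, c in enumerate(categories) if cat_matrix[i, j])
        for cat in sorted(record_cats):
            flags.add(_weighted_choice(rng, CONTEXT_FLAG_CHOICES[cat]))
        if smo_mask[i]:
            for t in tokens:
                if not token_matrix[i, token_index[t]]:
                    continue
                if t == "transfusion_units":
                    units = 5 + _trunc_geom(rng, dist["p"], 0, max(0, dist["max"] - 5))
                elif t in default_vocabulary().measurement_tokens:
                    measurements[t] = _severe_draw(t, rng)
                else:
                    flags.add(t)
        if units == 0 and rng.random() < spec.nonsevere_transfusion_prob:
            units = _trunc_geom(rng, dist["p"], dist["min"], min(4, dist["max"]))
        # consistency layer: a HELLP flag implies thrombocytopenia at least
        # at screening severity (<100 000/mm3)
        if "hellp" in flags and "platelet_count_per_mm3" not in measurements:
            measurements["platelet_count_per_mm3"] = float(rng.integers(50_000, 100_000))
        records.append(
            PatientRecord(
                record_id=f"r{i + 1:0{width}d}",
                outcome="died" if died[i] else "survived",
                timing=_weighted_choice(rng, TIMING_CHOICES),
                condition_category=record_cats,
                flags=frozenset(flags),
                measurements=measurements,
                transfusion_units=int(units),
            )
        )
    return Cohort(
        records=records,
        live_births=spec.live_births,
        label=f"synthetic(seed={spec.seed})",
    )


# ---------------------------------------------------------------------------
# marginal recovery


@dataclass(frozen=True)
class MarginalCheck:
    parameter: str
    target: float
    observed: float
    n: int
    z: float
    flagged: bool


def _z_score(observed: float, target: float, n: int) -> float:
    if n == 0:
        return 0.0
    sd = math.sqrt(target * (1.0 - target) / n)
    if sd == 0.0:
        return 0.0 if observed == target else math.inf
    return (observed - target) / sd


def _who_indicator_satisfied(record: PatientRecord, token: str) -> bool:
    """Whether a record satisfies the WHO severity indicator linked to a
    generator token (flag presence, threshold at WHO severity, or >= 5
    transfused units)."""
    if token == "transfusion_units":
        return record.transfusion_units >= 5
    vocab = default_vocabulary()
    if vocab.kind_of(token) != "measurement":
        return token in record.flags
    value = record.measurement(token)
    if value is None:
        return False
    tests = {
        "spo2_pct_sustained_60min": value < 90,
        "ph": value < 7.1,
        "pao2_fio2_mmHg": value < 200,
        "lactate_mmol_L": value > 5,
        "creatinine_mg_dL": value >= 3.5,
        "platelet_count_per_mm3": value < 50_000,
        "bilirubin_mg_dL": value > 6.0,
        "respiratory_rate_per_min": value > 40 or value < 6,
    }
    return tests[token]


def recover_marginals(
    cohort: Cohort, spec: CohortSpec, z_limit: float = 4.0
) -> list[MarginalCheck]:
    """Observed vs target frequency for every spec probability.

    Deviations are standardised by the binomial SD at the relevant
    denominator; |z| > ``z_limit`` is flagged as a recovery failure.
    """
    n = len(cohort)
    checks: list[MarginalCheck] = []

    def add(parameter: str, target: float, observed: float, denom: int) -> None:
        z = _z_score(observed, target, denom)
        checks.append(
            MarginalCheck(parameter, target, observed, denom, z, abs(z) > z_limit)
        )

    who_positive = [
        res.positive for res in classify_cohort(cohort, load_builtin("who_2011"))
    ]
    smo_records = [r for r, pos in zip(cohort, who_positive) if pos]
    add("smo_fraction", spec.smo_fraction, len(smo_records) / n if n else 0.0, n)
    n_died = sum(1 for r in cohort if r.outcome == "died")
    add("death_fraction", spec.death_fraction, n_died / n if n else 0.0, n)
    for cat in sorted(spec.condition_prevalences):
        observed = sum(1 for r in cohort if cat in r.condition_category) / n if n else 0.0
        add(f"prevalence[{cat}]", spec.condition_prevalences[cat], observed, n)
    n_smo = len(smo_records)
    for token in sorted(spec.indicator_freqs_among_smo):
        observed = (
            sum(1 for r in smo_records if _who_indicator_satisfied(r, token)) / n_smo
            if n_smo
            else 0.0
        )
        add(f"indicator[{token}]", spec.indicator_freqs_among_smo[token], observed, n_smo)
    return checks
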