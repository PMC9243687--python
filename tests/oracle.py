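"""Independent brute-force reference evaluator.

Re-implements predicate evaluation and the combination rules naively —
every sub-expression is materialised (no short-circuiting), truth values
are combined by counting — so it shares no evaluation path with the
engine. Used as the equivalence oracle in property tests.
"""

from __future__ import annotations

import operator

import numpy as np

from mnmkit.criteria import AllOf, AnyOf, FlagPresent, RangeOut, Threshold
from mnmkit.model import PatientRecord

_CMP = {"<": operator.lt, "<=": operator.le, ">": operator.gt, ">=": operator.ge}


def naive_eval(expr, record: PatientRecord) -> bool:
    if isinstance(expr, FlagPresent):
        return expr.token in record.flags
    if isinstance(expr, Threshold):
        value = record.measurement(expr.token)
        if value is None:
            return False
        return _CMP[expr.cmp](value, expr.value)
    if isinstance(expr, RangeOut):
        value = record.measurement(expr.token)
        if value is None:
            return False
        return bool(value < expr.low) or bool(value > expr.high)
    if isinstance(expr, AllOf):
        values = [naive_eval(item, record) for item in expr.items]
        return sum(values) == len(values)
    if isinstance(expr, AnyOf):
        values = [naive_eval(item, record) for item in expr.items]
        return sum(values) > 0
    raise TypeError(type(expr))


def naive_classify(record: PatientRecord, criteria):
    """(positive, matched, verdict) computed without the engine."""
    truth = {p.predicate_id: naive_eval(p.expression, record) for p in criteria.predicates}
    matched = tuple(sorted(pid for pid, value in truth.items() if value))
    if criteria.combinator == "any_one":
        positive = len(matched) > 0
    else:
        section_hits: dict[str, int] = {}
        for p in criteria.predicates:
            section_hits[p.indian_section] = section_hits.get(p.indian_section, 0) + int(
                truth[p.predicate_id]
            )
        positive = (
            section_hits.get("clinical_finding", 0) > 0
            and section_hits.get("investigation", 0) > 0
            and section_hits.get("intervention", 0) > 0
        ) or section_hits.get("collapse", 0) > 0
    if record.outcome == "died":
        verdict = "maternal_death_identified" if positive else "maternal_death_missed"
    else:
        verdict = "near_miss" if positive else "negative"
    return positive, matched, verdict


_MEASUREMENT_RANGES = {
    "ph": (6.5, 7.6),
    "lactate_mmol_L": (0.5, 20.0),
    "creatinine_mg_dL": (0.3, 9.0),
    "bilirubin_mg_dL": (0.2, 25.0),
    "platelet_count_per_mm3": (3_000, 400_000),
    "spo2_pct_sustained_60min": (50.0, 100.0),
    "pao2_fio2_mmHg": (50.0, 500.0),
    "respiratory_rate_per_min": (0.0, 70.0),
    "urine_output_mL_24h": (0.0, 3000.0),
    "urea_mmol_L": (2.0, 40.0),
}


def random_record(rng: np.random.Generator, vocab, record_id: str) -> PatientRecord:
    """A random record straddling every predicate's decision boundary:
    sparse flags, measurements missing ~60% of the time and otherwise
    uniform across a range containing the thresholds."""
    flags = frozenset(f for f in sorted(vocab.flag_tokens) if rng.random() < 0.05)
    measurements = {
        token: float(rng.uniform(lo, hi))
        for token, (lo, hi) in _MEASUREMENT_RANGES.items()
        if rng.random() < 0.4
    }
    units = int(rng.integers(0, 11)) if rng.random() < 0.5 else 0
    return PatientRecord(
        record_id=record_id,
        outcome="died" if rng.random() < 0.1 else "survived",
        flags=flags,
        measurements=measurements,
        transfusion_units=units,
    )
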