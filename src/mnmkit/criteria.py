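"""Declarative criteria engine for maternal near-miss classification.

Each criteria set is a named collection of predicates over the indicator
vocabulary, plus a combination rule. Most sets classify a woman on any
single satisfied predicate (``any_one``); the Indian national criteria use
a three-section rule (``indian_sections``): at least one satisfied
criterion in each of clinical findings, investigations and interventions,
or any single criterion signifying cardiorespiratory collapse.

Missingness rule: a threshold or range predicate over a measurement that
was never taken evaluates False — an absent laboratory value cannot assert
severity. This is what lets clinically oriented sets run where laboratory
services are not uniformly available.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .model import Cohort, PatientRecord
from .vocabulary import Vocabulary, default_vocabulary

BUILTIN_SET_IDS = (
    "cdc_2017",
    "global_network_2016",
    "indian_2014",
    "mantel_1998",
    "pltc_screen",
    "roberts_2008",
    "waterstone_2001",
    "who_2011",
)

#: The seven near-miss criteria sets (the PLTC screen is the inclusion tier,
#: not a near-miss definition).
NEAR_MISS_SET_IDS = tuple(s for s in BUILTIN_SET_IDS if s != "pltc_screen")

CATEGORIES = ("clinical", "laboratory", "management")
INDIAN_SECTIONS = ("clinical_finding", "investigation", "intervention", "collapse")
PLTC_CATEGORIES = ("haemorrhagic", "hypertensive", "systemic", "management")
COMPARATORS = ("<", "<=", ">", ">=")

VERDICTS = ("near_miss", "maternal_death_identified", "maternal_death_missed", "negative")


class ConfigurationError(ValueError):
    """A criteria document or pipeline configuration is malformed."""


# --------------------------------------------------------------------------
# expression grammar


@dataclass(frozen=True)
class FlagPresent:
    token: str


@dataclass(frozen=True)
class Threshold:
    token: str
    cmp: str
    value: float

    def __post_init__(self):
        if self.cmp not in COMPARATORS:
            raise ConfigurationError(f"unknown comparator {self.cmp!r}")
        if not (self.value == self.value and abs(self.value) != float("inf")):
            raise ConfigurationError("threshold value must be finite")


@dataclass(frozen=True)
class RangeOut:
    """True when the measurement falls outside (low, high)."""

    token: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ConfigurationError("range_out requires low < high")


@dataclass(frozen=True)
class AllOf:
    items: tuple


@dataclass(frozen=True)
class AnyOf:
    items: tuple


Expression = FlagPresent | Threshold | RangeOut | AllOf | AnyOf


def parse_expression(doc: dict) -> Expression:
    """Parse the YAML expression grammar.

    ``{flag: token}`` | ``{measurement: token, cmp: op, value: x}`` |
    ``{measurement: token, outside: [low, high]}`` |
    ``{all_of: [...]}`` | ``{any_of: [...]}``
    """
    if not isinstance(doc, dict):
        raise ConfigurationError(f"expression must be a mapping, got {doc!r}")
    if "flag" in doc:
        return FlagPresent(doc["flag"])
    if "all_of" in doc:
        return AllOf(tuple(parse_expression(d) for d in doc["all_of"]))
    if "any_of" in doc:
        return AnyOf(tuple(parse_expression(d) for d in doc["any_of"]))
    if "measurement" in doc:
        if "outside" in doc:
            low, high = doc["outside"]
            return RangeOut(doc["measurement"], float(low), float(high))
        return Threshold(doc["measurement"], doc["cmp"], float(doc["value"]))
    raise ConfigurationError(f"unrecognised expression {doc!r}")


def expression_to_dict(expr: Expression) -> dict:
    """Inverse of :func:`parse_expression` (used by the report writers)."""
    if isinstance(expr, FlagPresent):
        return {"flag": expr.token}
    if isinstance(expr, Threshold):
        return {"measurement": expr.token, "cmp": expr.cmp, "value": expr.value}
    if isinstance(expr, RangeOut):
        return {"measurement": expr.token, "outside": [expr.low, expr.high]}
    if isinstance(expr, AllOf):
        return {"all_of": [expression_to_dict(i) for i in expr.items]}
    if isinstance(expr, AnyOf):
        return {"any_of": [expression_to_dict(i) for i in expr.items]}
    raise TypeError(type(expr))


def expression_tokens(expr: Expression) -> set[str]:
    if isinstance(expr, (FlagPresent, Threshold, RangeOut)):
        return {expr.token}
    return set().union(*(expression_tokens(i) for i in expr.items))


_CMP = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def _evaluate(expr: Expression, record: PatientRecord) -> bool:
    if isinstance(expr, FlagPresent):
        return expr.token in record.flags
    if isinstance(expr, Threshold):
        value = record.measurement(expr.token)
        return value is not None and _CMP[expr.cmp](value, expr.value)
    if isinstance(expr, RangeOut):
        value = record.measurement(expr.token)
        return value is not None and (value < expr.low or value > expr.high)
    if isinstance(expr, AllOf):
        return all(_evaluate(i, record) for i in expr.items)
    if isinstance(expr, AnyOf):
        return any(_evaluate(i, record) for i in expr.items)
    raise TypeError(type(expr))


# --------------------------------------------------------------------------
# predicates and criteria sets


@dataclass(frozen=True)
class Predicate:
    predicate_id: str
    category: str
    expression: Expression
    indian_section: str | None = None
    pltc_category: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConfigurationError(
                f"predicate {self.predicate_id!r}: unknown category {self.category!r}"
            )
        if self.indian_section is not None and self.indian_section not in INDIAN_SECTIONS:
            raise ConfigurationError(
                f"predicate {self.predicate_id!r}: unknown section {self.indian_section!r}"
            )
        if self.pltc_category is not None and self.pltc_category not in PLTC_CATEGORIES:
            raise ConfigurationError(
                f"predicate {self.predicate_id!r}: unknown PLTC category "
                f"{self.pltc_category!r}"
            )


@dataclass(frozen=True)
class CriteriaSet:
    set_id: str
    combinator: str
    predicates: tuple
    label: str = ""

    def __post_init__(self):
        if self.combinator not in ("any_one", "indian_sections"):
            raise ConfigurationError(f"unknown combinator {self.combinator!r}")
        seen = set()
        for pred in self.predicates:
            if pred.predicate_id in seen:
                raise ConfigurationError(f"duplicate predicate_id {pred.predicate_id!r}")
            seen.add(pred.predicate_id)
        if self.combinator == "indian_sections":
            missing = [p.predicate_id for p in self.predicates if p.indian_section is None]
            if missing:
                raise ConfigurationError(
                    f"{self.set_id}: indian_sections requires a section on every "
                    f"predicate; missing on {missing}"
                )

    def tokens(self) -> set[str]:
        return set().union(*(expression_tokens(p.expression) for p in self.predicates))

    def check_vocabulary(self, vocabulary: Vocabulary) -> None:
        """Raise ConfigurationError naming the first predicate that
        references a token outside the vocabulary."""
        for pred in self.predicates:
            for token in sorted(expression_tokens(pred.expression)):
                if token not in vocabulary:
                    raise ConfigurationError(
                        f"{self.set_id}/{pred.predicate_id}: unknown token {token!r}"
                    )


@dataclass(frozen=True)
class ClassificationResult:
    record_id: str
    set_id: str
    positive: bool
    matched: tuple
    verdict: str


# --------------------------------------------------------------------------
# loading


def criteria_from_dict(doc: dict, vocabulary: Vocabulary | None = None) -> CriteriaSet:
    try:
        predicates = tuple(
            Predicate(
                predicate_id=p["predicate_id"],
                category=p["category"],
                expression=parse_expression(p["expression"]),
                indian_section=p.get("indian_section"),
                pltc_category=p.get("pltc_category"),
            )
            for p in doc["predicates"]
        )
        criteria = CriteriaSet(
            set_id=doc["set_id"],
            combinator=doc.get("combinator", "any_one"),
            predicates=predicates,
            label=doc.get("label", doc["set_id"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"criteria document missing field {exc}") from exc
    criteria.check_vocabulary(vocabulary or default_vocabulary())
    return criteria


def load_criteria_yaml(path: str | Path, vocabulary: Vocabulary | None = None) -> CriteriaSet:
    """Load a user-supplied criteria set in the shipped YAML grammar."""
    doc = yaml.safe_load(Path(path).read_text())
    return criteria_from_dict(doc, vocabulary)


_BUILTIN_CACHE: dict[str, CriteriaSet] = {}


def load_builtin(set_id: str) -> CriteriaSet:
    """Load one of the shipped criteria sets by id."""
    if set_id not in BUILTIN_SET_IDS:
        raise ConfigurationError(
            f"unknown criteria set {set_id!r}; available: {', '.join(BUILTIN_SET_IDS)}"
        )
    if set_id not in _BUILTIN_CACHE:
        text = (resources.files("mnmkit") / "data" / "criteria" / f"{set_id}.yaml").read_text()
        _BUILTIN_CACHE[set_id] = criteria_from_dict(yaml.safe_load(text))
    return _BUILTIN_CACHE[set_id]


def load_all_builtin(include_pltc: bool = False) -> list[CriteriaSet]:
    ids = BUILTIN_SET_IDS if include_pltc else NEAR_MISS_SET_IDS
    return [load_builtin(s) for s in ids]


# --------------------------------------------------------------------------
# evaluation


def evaluate_predicate(record: PatientRecord, predicate: Predicate) -> bool:
    """Deterministic truth value of one predicate on one record."""
    try:
        return _evaluate(predicate.expression, record)
    except KeyError as exc:  # unknown token surfacing at evaluation time
        raise ConfigurationError(
            f"predicate {predicate.predicate_id!r}: unknown token {exc}"
        ) from exc


def _verdict(positive: bool, outcome: str) -> str:
    if outcome == "died":
        return "maternal_death_identified" if positive else "maternal_death_missed"
    return "near_miss" if positive else "negative"


def classify(record: PatientRecord, criteria: CriteriaSet) -> ClassificationResult:
    """Classify one record under one criteria set, with provenance.

    ``matched`` lists every satisfied predicate, sorted by predicate_id so
    outputs are byte-stable. Positivity follows the set's combinator; the
    verdict combines positivity with the vital outcome.
    """
    matched = tuple(
        sorted(
            p.predicate_id
            for p in criteria.predicates
            if evaluate_predicate(record, p)
        )
    )
    if criteria.combinator == "any_one":
        positive = bool(matched)
    else:  # indian_sections
        matched_set = set(matched)
        sections_hit = {
            p.indian_section for p in criteria.predicates if p.predicate_id in matched_set
        }
        positive = (
            {"clinical_finding", "investigation", "intervention"} <= sections_hit
            or "collapse" in sections_hit
        )
    return ClassificationResult(
        record_id=record.record_id,
        set_id=criteria.set_id,
        positive=positive,
        matched=matched,
        verdict=_verdict(positive, record.outcome),
    )


def classify_cohort(cohort: Cohort, criteria: CriteriaSet) -> list[ClassificationResult]:
    """One result per record, input order preserved; pure in its inputs."""
    results = []
    for record in cohort:
        try:
            results.append(classify(record, criteria))
        except ConfigurationError as exc:
            raise ConfigurationError(f"record {record.record_id!r}: {exc}") from exc
    return results


def pltc_screen(record: PatientRecord, screen: CriteriaSet | None = None) -> set[str]:
    """WHO potentially-life-threatening-condition screen.

    Returns every PLTC category (haemorrhagic, hypertensive, systemic,
    management) with at least one satisfied screening predicate. Screening
    thresholds are deliberately looser than near-miss thresholds.
    """
    screen = screen or load_builtin("pltc_screen")
    return {
        p.pltc_category
        for p in screen.predicates
        if p.pltc_category is not None and evaluate_predicate(record, p)
    }
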