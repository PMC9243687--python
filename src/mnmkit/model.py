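"""Patient records and cohorts.

A :class:`PatientRecord` is one woman's admission: the indicator flags
observed, laboratory measurements actually taken (absence of a value is
representable and distinct from any number), units of blood transfused,
and the vital outcome. A :class:`Cohort` is an ordered collection of
records together with the live-birth denominator, which is an explicit
surveillance parameter — live births routinely exceed the screened cohort
size, so it is never inferred from the number of rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .vocabulary import (
    CONDITION_CATEGORIES,
    TIMING_VALUES,
    Vocabulary,
    default_vocabulary,
)

OUTCOMES = ("survived", "died")

#: transfusion volume is exposed both as a record attribute and as the
#: pseudo-measurement token used in threshold predicates.
TRANSFUSION_TOKEN = "transfusion_units"


@dataclass(frozen=True)
class Violation:
    """One validation problem: the offending field and token, plus prose."""

    field: str
    token: str
    message: str


@dataclass
class PatientRecord:
    record_id: str
    outcome: str = "survived"
    timing: str | None = None
    condition_category: frozenset = frozenset()
    flags: frozenset = frozenset()
    measurements: dict = field(default_factory=dict)
    transfusion_units: int = 0

    def __post_init__(self) -> None:
        self.condition_category = frozenset(self.condition_category)
        self.flags = frozenset(self.flags)
        measurements = dict(self.measurements)
        # transfusion_units and measurements["transfusion_units"] are the
        # same datum; normalise onto the attribute.
        if TRANSFUSION_TOKEN in measurements:
            units = measurements.pop(TRANSFUSION_TOKEN)
            if self.transfusion_units not in (0, units):
                raise ValueError(
                    f"record {self.record_id!r}: transfusion_units given twice "
                    f"with conflicting values"
                )
            self.transfusion_units = units
        self.measurements = measurements

    def measurement(self, token: str) -> float | None:
        """Value of a measurement token, or None when not observed.

        ``transfusion_units`` is always observed (0 = none recorded).
        """
        if token == TRANSFUSION_TOKEN:
            return float(self.transfusion_units)
        return self.measurements.get(token)


def validate_record(
    record: PatientRecord, vocabulary: Vocabulary | None = None
) -> list[Violation]:
    """Check a record against the vocabulary; report-style, never raises.

    Returns an empty list iff the record satisfies every invariant:
    flags drawn from the flag vocabulary, measurement keys from the
    measurement vocabulary with finite numeric values, a non-negative
    integer transfusion volume, and enum fields within their domains.
    """
    vocabulary = vocabulary or default_vocabulary()
    violations: list[Violation] = []
    if record.outcome not in OUTCOMES:
        violations.append(
            Violation("outcome", str(record.outcome), f"outcome must be one of {OUTCOMES}")
        )
    if record.timing is not None and record.timing not in TIMING_VALUES:
        violations.append(
            Violation("timing", str(record.timing), f"timing must be one of {TIMING_VALUES}")
        )
    for cat in sorted(record.condition_category):
        if cat not in CONDITION_CATEGORIES:
            violations.append(
                Violation("condition_category", cat, "unknown condition category")
            )
    flag_tokens = vocabulary.flag_tokens
    for flag in sorted(record.flags):
        if flag not in flag_tokens:
            violations.append(Violation("flags", flag, "token not in flag vocabulary"))
    meas_tokens = vocabulary.measurement_tokens
    for token in sorted(record.measurements):
        value = record.measurements[token]
        if token not in meas_tokens:
            violations.append(
                Violation("measurements", token, "token not in measurement vocabulary")
            )
        elif not isinstance(value, (int, float)) or not math.isfinite(value):
            violations.append(
                Violation("measurements", token, f"non-finite or non-numeric value {value!r}")
            )
    units = record.transfusion_units
    if not isinstance(units, int) or isinstance(units, bool) or units < 0:
        violations.append(
            Violation(
                TRANSFUSION_TOKEN,
                str(units),
                "transfusion_units must be a non-negative integer",
            )
        )
    return violations


@dataclass
class Cohort:
    """Ordered patient records plus the live-birth denominator."""

    records: list
    live_births: int
    label: str = "cohort"

    def __post_init__(self) -> None:
        self.records = list(self.records)
        if self.live_births < 1:
            raise ValueError("live_births must be >= 1")
        seen: set[str] = set()
        for record in self.records:
            if record.record_id in seen:
                raise ValueError(f"duplicate record_id {record.record_id!r}")
            seen.add(record.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def outcomes(self) -> dict[str, str]:
        return {r.record_id: r.outcome for r in self.records}

    def validate(self, vocabulary: Vocabulary | None = None) -> dict[str, list[Violation]]:
        """Per-record validation reports for records that have problems."""
        vocabulary = vocabulary or default_vocabulary()
        reports = {}
        for record in self.records:
            violations = validate_record(record, vocabulary)
            if violations:
                reports[record.record_id] = violations
        return reports
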