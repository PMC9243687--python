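"""Transfusion-threshold sensitivity analysis.

Blood transfusion is the indicator on which near-miss criteria sets differ
most consequentially: the WHO tool requires >= 5 units of blood or packed
red cells, while several other systems count any volume. In settings where
moderate-to-severe anaemia is common, women are transfused one or a few
units without a life-threatening event, so an any-volume criterion can
substantially inflate near-miss counts. This module buckets a cohort by
units transfused and recomputes classification under a sweep of
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .criteria import (
    ConfigurationError,
    CriteriaSet,
    Threshold,
    classify_cohort,
)
from .model import Cohort, TRANSFUSION_TOKEN


@dataclass(frozen=True)
class TransfusionStratum:
    """One bucket of the transfusion curve.

    ``units`` is the exact unit count, or the terminal bucket ``>= k``
    when ``terminal`` is set. ``n_positive_by_set`` counts women the
    criteria set identifies in the bucket (near misses plus identified
    deaths).
    """

    units: int
    terminal: bool
    n_women: int
    n_positive_by_set: Mapping[str, int]

    @property
    def label(self) -> str:
        return f">={self.units}" if self.terminal else str(self.units)


@dataclass(frozen=True)
class TransfusionCurve:
    strata: tuple

    @property
    def n_transfused(self) -> int:
        return sum(s.n_women for s in self.strata)


def transfusion_curve(
    cohort: Cohort,
    criteria_sets: Sequence[CriteriaSet],
    max_units: int = 5,
) -> TransfusionCurve:
    """Bucket transfused records by unit count, classifying each bucket.

    Buckets are 1, 2, ..., max_units - 1 and a terminal ``>= max_units``;
    records with 0 units are excluded. Empty buckets are retained with zero
    counts so the curve shape is stable across cohorts.
    """
    if max_units < 1:
        raise ValueError("max_units must be >= 1")
    positives: dict[str, set[str]] = {}
    for criteria in criteria_sets:
        positives[criteria.set_id] = {
            r.record_id for r in classify_cohort(cohort, criteria) if r.positive
        }
    strata = []
    for units in range(1, max_units + 1):
        terminal = units == max_units
        members = [
            r
            for r in cohort
            if (r.transfusion_units >= units if terminal else r.transfusion_units == units)
        ]
        if terminal or members or units < max_units:
            strata.append(
                TransfusionStratum(
                    units=units,
                    terminal=terminal,
                    n_women=len(members),
                    n_positive_by_set={
                        set_id: sum(1 for r in members if r.record_id in ids)
                        for set_id, ids in positives.items()
                    },
                )
            )
    if len(cohort) == 0:
        return TransfusionCurve(strata=())
    return TransfusionCurve(strata=tuple(strata))


def _find_transfusion_predicate(criteria: CriteriaSet):
    hits = [
        p
        for p in criteria.predicates
        if isinstance(p.expression, Threshold) and p.expression.token == TRANSFUSION_TOKEN
    ]
    if len(hits) != 1:
        raise ConfigurationError(
            f"{criteria.set_id}: threshold sweep needs exactly one transfusion "
            f"threshold predicate, found {len(hits)}"
        )
    return hits[0]


def with_transfusion_threshold(criteria: CriteriaSet, threshold: int) -> CriteriaSet:
    """Copy of ``criteria`` with its transfusion predicate set to >= threshold."""
    target = _find_transfusion_predicate(criteria)
    new_pred = replace(
        target, expression=Threshold(TRANSFUSION_TOKEN, ">=", float(threshold))
    )
    predicates = tuple(
        new_pred if p.predicate_id == target.predicate_id else p
        for p in criteria.predicates
    )
    return replace(criteria, predicates=predicates)


def threshold_sweep(
    cohort: Cohort, base_set: CriteriaSet, thresholds: Sequence[int]
) -> dict[int, int]:
    """Near-miss counts as the transfusion cut-off varies.

    For each t, the base set's single transfusion threshold predicate is
    replaced by ``transfusion_units >= t`` (all other predicates untouched)
    and surviving positives are counted.
    """
    _find_transfusion_predicate(base_set)  # fail fast on misconfiguration
    counts = {}
    for t in thresholds:
        modified = with_transfusion_threshold(base_set, t)
        counts[int(t)] = sum(
            1 for r in classify_cohort(cohort, modified) if r.verdict == "near_miss"
        )
    return counts
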