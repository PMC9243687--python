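"""WHO near-miss process indicators and the cross-criteria comparison.

Definitions (LB = live births, MNM = maternal near misses, MD = maternal
deaths identified by the criteria set under study):

* maternal near-miss ratio        = MNM / LB x 1000
* severe maternal outcome ratio   = (MNM + MD) / LB x 1000
* mortality index                 = MD / (MNM + MD) x 100
* MNM:MD ratio                    = MNM / MD

A lower mortality index and a higher MNM:MD ratio indicate higher quality
of care. Per criteria set, only the deaths that set itself identifies
enter SMO and the quality indices; deaths it fails to flag are reported
separately as missed. All values are carried at full precision; a
presentation rounding (half away from zero) to the conventional printed
precision is available alongside, never instead.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .criteria import (
    ClassificationResult,
    CriteriaSet,
    classify_cohort,
    load_builtin,
)
from .model import Cohort
from .vocabulary import CONDITION_CATEGORIES


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables,
    unlike banker's rounding)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IndicatorReport:
    """Cohort-level counts and the four WHO process indicators for one set."""

    set_id: str
    n_near_miss: int
    n_deaths_identified: int
    n_deaths_missed: int
    n_smo: int
    live_births: int
    mnm_ratio_per_1000: float
    smo_ratio_per_1000: float
    mortality_index_pct: float
    mnm_to_md_ratio: float | None  # None == undefined (no identified deaths)

    def presentation(self) -> dict:
        """Full-precision values plus rounded twins at printed precision."""
        doc = asdict(self)
        doc["rounded"] = {
            "mnm_ratio_per_1000": round_half_away(self.mnm_ratio_per_1000, 1),
            "smo_ratio_per_1000": round_half_away(self.smo_ratio_per_1000, 1),
            "mortality_index_pct": round_half_away(self.mortality_index_pct, 1),
            "mnm_to_md_ratio": (
                None if self.mnm_to_md_ratio is None
                else round_half_away(self.mnm_to_md_ratio, 2)
            ),
        }
        return doc


def report_from_counts(
    set_id: str,
    n_near_miss: int,
    n_deaths_identified: int,
    live_births: int,
    n_deaths_missed: int = 0,
) -> IndicatorReport:
    """Build an :class:`IndicatorReport` from raw counts.

    This is the closed-form core: feeding any published comparison table's
    counts through it reproduces that table's derived indicator cells.
    """
    if live_births < 1:
        raise ValueError("live_births must be >= 1")
    for name, n in (
        ("n_near_miss", n_near_miss),
        ("n_deaths_identified", n_deaths_identified),
        ("n_deaths_missed", n_deaths_missed),
    ):
        if n < 0:
            raise ValueError(f"{name} must be non-negative")
    n_smo = n_near_miss + n_deaths_identified
    return IndicatorReport(
        set_id=set_id,
        n_near_miss=n_near_miss,
        n_deaths_identified=n_deaths_identified,
        n_deaths_missed=n_deaths_missed,
        n_smo=n_smo,
        live_births=live_births,
        mnm_ratio_per_1000=n_near_miss / live_births * 1000,
        smo_ratio_per_1000=n_smo / live_births * 1000,
        mortality_index_pct=(n_deaths_identified / n_smo * 100 if n_smo > 0 else 0.0),
        mnm_to_md_ratio=(
            n_near_miss / n_deaths_identified if n_deaths_identified > 0 else None
        ),
    )


def compute_report(
    results: Sequence[ClassificationResult],
    outcomes: Mapping[str, str],
    live_births: int,
    set_id: str | None = None,
) -> IndicatorReport:
    """Tally classification results into an :class:`IndicatorReport`.

    ``outcomes`` maps record_id -> survived/died and must cover every
    result; it is used to cross-check that identified + missed deaths
    conserve the total number of deaths.
    """
    if live_births < 1:
        raise ValueError("live_births must be >= 1")
    n_near_miss = n_identified = n_missed = 0
    for result in results:
        if result.record_id not in outcomes:
            raise ValueError(f"no outcome for record {result.record_id!r}")
        if result.verdict == "near_miss":
            n_near_miss += 1
        elif result.verdict == "maternal_death_identified":
            n_identified += 1
        elif result.verdict == "maternal_death_missed":
            n_missed += 1
    n_died = sum(1 for r in results if outcomes[r.record_id] == "died")
    if n_identified + n_missed != n_died:
        raise ValueError("verdicts inconsistent with outcomes mapping")
    sid = set_id or (results[0].set_id if results else "unknown")
    return report_from_counts(sid, n_near_miss, n_identified, live_births, n_missed)


def compute_mmr(n_deaths: int, live_births: int) -> float:
    """Maternal mortality ratio per 100 000 live births."""
    if live_births < 1:
        raise ValueError("live_births must be >= 1")
    return n_deaths / live_births * 100_000


def pltc_incidence(n_pltc: int, live_births: int) -> float:
    """Potentially-life-threatening-condition incidence per 1000 live births."""
    if live_births < 1:
        raise ValueError("live_births must be >= 1")
    return n_pltc / live_births * 1000


@dataclass(frozen=True)
class CaseFatalityRow:
    """Case fatality among women with one potentially life-threatening
    condition category: deaths / all women with that condition x 100."""

    condition: str
    n_pltc: int
    n_near_miss: int
    n_deaths: int
    case_fatality_pct: float


def case_fatality_table(
    cohort: Cohort,
    condition_categories: Iterable[str] = CONDITION_CATEGORIES,
    criteria: CriteriaSet | None = None,
) -> list[CaseFatalityRow]:
    """One row per condition category with a non-zero denominator.

    Condition categories overlap (a woman may carry several), so rows need
    not sum to the cohort size. Near misses per row are counted under
    ``criteria`` (the WHO near-miss tool by default).
    """
    criteria = criteria or load_builtin("who_2011")
    positive_survivors = {
        res.record_id
        for res in classify_cohort(cohort, criteria)
        if res.verdict == "near_miss"
    }
    rows = []
    for condition in condition_categories:
        members = [r for r in cohort if condition in r.condition_category]
        if not members:
            continue
        n_deaths = sum(1 for r in members if r.outcome == "died")
        rows.append(
            CaseFatalityRow(
                condition=condition,
                n_pltc=len(members),
                n_near_miss=sum(1 for r in members if r.record_id in positive_survivors),
                n_deaths=n_deaths,
                case_fatality_pct=n_deaths / len(members) * 100,
            )
        )
    return rows


def compare_criteria(
    cohort: Cohort, criteria_sets: Sequence[CriteriaSet]
) -> list[IndicatorReport]:
    """One :class:`IndicatorReport` per criteria set over the identical
    cohort, ordered by set_id (the published comparison-table shape)."""
    outcomes = cohort.outcomes()
    reports = []
    for criteria in sorted(criteria_sets, key=lambda c: c.set_id):
        results = classify_cohort(cohort, criteria)
        reports.append(
            compute_report(results, outcomes, cohort.live_births, set_id=criteria.set_id)
        )
    return reports
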