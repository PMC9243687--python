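"""End-to-end surveillance pipeline: input (file or simulation), per-record
classification under selected criteria sets, indicator reports, the
cross-criteria comparison, and the transfusion curve. Deterministic given
the same inputs and seed."""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

from . import __version__
from .criteria import (
    BUILTIN_SET_IDS,
    NEAR_MISS_SET_IDS,
    ConfigurationError,
    classify_cohort,
    load_builtin,
)
from .indicators import compare_criteria, round_half_away
from .io import read_cohort, write_cohort
from .model import Cohort
from .synthetic import CohortSpec, generate
from .transfusion import TransfusionCurve, transfusion_curve
from .vocabulary import default_vocabulary

log = logging.getLogger("mnmkit")


def _resolve_sets(selected) -> list:
    if selected in (None, "all"):
        ids = list(NEAR_MISS_SET_IDS)
    else:
        ids = list(selected)
    for set_id in ids:
        if set_id not in BUILTIN_SET_IDS:
            raise ConfigurationError(
                f"unknown criteria set {set_id!r}; available: {', '.join(BUILTIN_SET_IDS)}"
            )
    return [load_builtin(s) for s in ids]


def _load_input(config: dict, seed: int | None) -> tuple[Cohort, dict]:
    source = config.get("input")
    if not isinstance(source, dict):
        raise ConfigurationError("config must carry an 'input' mapping")
    if "simulate" in source:
        spec_doc = dict(source["simulate"] or {})
        if seed is not None:
            spec_doc["seed"] = seed
        unknown = set(spec_doc) - set(CohortSpec.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown CohortSpec fields: {sorted(unknown)}")
        spec = CohortSpec(**spec_doc)
        try:
            spec.validate()
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from exc
        return generate(spec), {"simulate": spec.to_dict()}
    if "csv" in source:
        if "live_births" not in source:
            raise ConfigurationError(
                "live_births is mandatory for a file cohort: it is the live-birth "
                "denominator, not the row count"
            )
        cohort = read_cohort(source["csv"], live_births=int(source["live_births"]))
        return cohort, {"csv": str(source["csv"]), "live_births": cohort.live_births}
    raise ConfigurationError("input must name either 'csv' or 'simulate'")


def write_classification_csv(cohort: Cohort, results_by_set: dict, path: Path) -> None:
    set_ids = sorted(results_by_set)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        header = ["record_id", "outcome"]
        for set_id in set_ids:
            header += [f"{set_id}_positive", f"{set_id}_verdict", f"{set_id}_matched"]
        writer.writerow(header)
        for i, record in enumerate(cohort):
            row = [record.record_id, record.outcome]
            for set_id in set_ids:
                res = results_by_set[set_id][i]
                row += [int(res.positive), res.verdict, "|".join(res.matched)]
            writer.writerow(row)


def write_comparison(reports, out_json: Path, out_csv: Path) -> None:
    docs = [r.presentation() for r in reports]
    out_json.write_text(json.dumps(docs, indent=2) + "\n", encoding="utf-8")
    with open(out_csv, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "set_id", "n_smo", "n_near_miss", "n_deaths_identified",
                "n_deaths_missed", "smo_ratio_per_1000", "mnm_ratio_per_1000",
                "mortality_index_pct", "mnm_to_md_ratio",
            ]
        )
        for r in reports:
            writer.writerow(
                [
                    r.set_id, r.n_smo, r.n_near_miss, r.n_deaths_identified,
                    r.n_deaths_missed,
                    round_half_away(r.smo_ratio_per_1000, 1),
                    round_half_away(r.mnm_ratio_per_1000, 1),
                    round_half_away(r.mortality_index_pct, 1),
                    "" if r.mnm_to_md_ratio is None else round_half_away(r.mnm_to_md_ratio, 2),
                ]
            )


def write_curve_csv(curve: TransfusionCurve, path: Path) -> None:
    set_ids = sorted(curve.strata[0].n_positive_by_set) if curve.strata else []
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["units", "n_women"] + set_ids)
        for stratum in curve.strata:
            writer.writerow(
                [stratum.label, stratum.n_women]
                + [stratum.n_positive_by_set[s] for s in set_ids]
            )


def run_pipeline(config: dict, out_dir: str | Path | None = None, seed: int | None = None) -> Path:
    """Run the full pipeline and write artifacts under the output directory.

    Returns the output directory. Raises ConfigurationError before any
    computation if the configuration is malformed.
    """
    out = Path(out_dir or config.get("out", "mnmkit_out"))
    criteria_sets = _resolve_sets(config.get("criteria"))
    cohort, provenance_input = _load_input(config, seed)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)

    log.info("cohort %s: %d records, %d live births", cohort.label, len(cohort), cohort.live_births)
    if "simulate" in provenance_input:
        write_cohort(cohort, out / "cohort.csv")

    results_by_set = {c.set_id: classify_cohort(cohort, c) for c in criteria_sets}
    write_classification_csv(cohort, results_by_set, out / "classification.csv")

    reports = compare_criteria(cohort, criteria_sets)
    for report in reports:
        (out / "reports" / f"{report.set_id}.json").write_text(
            json.dumps(report.presentation(), indent=2) + "\n", encoding="utf-8"
        )
        log.info(
            "%s: SMO=%d MNM=%d missed_deaths=%d",
            report.set_id, report.n_smo, report.n_near_miss, report.n_deaths_missed,
        )
    write_comparison(reports, out / "comparison.json", out / "comparison.csv")

    curve = transfusion_curve(cohort, criteria_sets, max_units=int(config.get("max_units", 5)))
    write_curve_csv(curve, out / "transfusion_curve.csv")

    provenance = {
        "mnmkit_version": __version__,
        "vocabulary_version": default_vocabulary().version,
        "seed": seed,
        "input": provenance_input,
        "criteria": [c.set_id for c in criteria_sets],
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2) + "\n", encoding="utf-8"
    )
    log.info("artifacts written to %s", out)
    return out
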