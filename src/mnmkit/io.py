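"""CSV cohort dialect: one row per woman.

Columns: ``record_id``, ``outcome`` (survived|died), ``timing`` (optional),
``condition_category`` (semicolon-joined), one 0/1 column per flag token
(empty = 0), one column per measurement token (empty = missing), and
``transfusion_units`` (integer, empty = 0). Header row mandatory, UTF-8,
comma separator, "." decimal. Unknown columns are rejected unless
``allow_extra``.

An optional first-line units directive declares columns supplied in
µmol/L, converted to the canonical mg/dL at ingest::

    # units: creatinine_mg_dL=umol/L, bilirubin_mg_dL=umol/L

The live-birth denominator is an explicit parameter of
:func:`read_cohort` — it is a surveillance denominator, not the row count.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .model import Cohort, PatientRecord, TRANSFUSION_TOKEN, validate_record
from .vocabulary import UMOL_PER_L_DIVISORS, Vocabulary, default_vocabulary

FIXED_COLUMNS = ("record_id", "outcome", "timing", "condition_category")


class CohortParseError(ValueError):
    """Unparseable cell or malformed file; message carries row and column."""


class CohortValidationError(ValueError):
    """Aggregated per-row validation failures."""

    def __init__(self, reports):
        self.reports = reports  # list of (row_number, record_id, [Violation])
        lines = [
            f"row {row} ({rid!r}): {v.field}/{v.token}: {v.message}"
            for row, rid, violations in reports
            for v in violations
        ]
        super().__init__("cohort validation failed:\n" + "\n".join(lines))


def _columns(vocabulary: Vocabulary) -> list[str]:
    flags = sorted(vocabulary.flag_tokens)
    measurements = sorted(vocabulary.measurement_tokens - {TRANSFUSION_TOKEN})
    return list(FIXED_COLUMNS) + flags + measurements + [TRANSFUSION_TOKEN]


def write_cohort(cohort: Cohort, path: str | Path, vocabulary: Vocabulary | None = None) -> None:
    """Write a cohort in the CSV dialect (full column set, byte-stable)."""
    vocabulary = vocabulary or default_vocabulary()
    columns = _columns(vocabulary)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for record in cohort:
            row = []
            for col in columns:
                if col == "record_id":
                    row.append(record.record_id)
                elif col == "outcome":
                    row.append(record.outcome)
                elif col == "timing":
                    row.append(record.timing or "")
                elif col == "condition_category":
                    row.append(";".join(sorted(record.condition_category)))
                elif col == TRANSFUSION_TOKEN:
                    row.append(str(record.transfusion_units))
                elif col in vocabulary.flag_tokens:
                    row.append("1" if col in record.flags else "")
                else:
                    value = record.measurements.get(col)
                    row.append("" if value is None else repr(float(value)))
            writer.writerow(row)


def _parse_units_directive(line: str) -> dict[str, str]:
    body = line.split(":", 1)[1]
    declared = {}
    for part in body.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise CohortParseError(f"malformed units directive entry {part!r}")
        col, unit = (s.strip() for s in part.split("=", 1))
        declared[col] = unit
    return declared


def read_cohort(
    path: str | Path,
    live_births: int,
    allow_extra: bool = False,
    label: str | None = None,
    vocabulary: Vocabulary | None = None,
) -> Cohort:
    """Read and validate a cohort CSV.

    Raises :class:`CohortParseError` (with row/column context) on
    unparseable content and :class:`CohortValidationError` with an
    aggregated report when rows violate record invariants.
    """
    vocabulary = vocabulary or default_vocabulary()
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as handle:
        first = handle.readline()
        unit_overrides: dict[str, str] = {}
        if first.lstrip().startswith("# units"):
            unit_overrides = _parse_units_directive(first)
            header_offset = 2
        else:
            handle.seek(0)
            header_offset = 1
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortParseError(f"{path}: empty file, header row is mandatory")
        rows = list(reader)

    known = set(_columns(vocabulary))
    unknown = [c for c in header if c not in known]
    if unknown and not allow_extra:
        raise CohortParseError(f"{path}: unknown columns {unknown} (use allow_extra to keep)")
    if "record_id" not in header or "outcome" not in header:
        raise CohortParseError(f"{path}: record_id and outcome columns are mandatory")
    for col, unit in unit_overrides.items():
        if unit not in ("umol/L", "umol_per_L"):
            raise CohortParseError(f"units directive: unsupported unit {unit!r} for {col!r}")
        if col not in UMOL_PER_L_DIVISORS:
            raise CohortParseError(f"units directive: no umol/L conversion for {col!r}")

    flag_tokens = vocabulary.flag_tokens
    measurement_tokens = vocabulary.measurement_tokens
    records = []
    failures = []
    for idx, cells in enumerate(rows):
        row_number = idx + header_offset + 1
        if len(cells) != len(header):
            raise CohortParseError(
                f"{path}:{row_number}: expected {len(header)} cells, found {len(cells)}"
            )
        data = dict(zip(header, cells))
        flags = set()
        measurements: dict[str, float] = {}
        units = 0
        for col, raw in data.items():
            raw = raw.strip()
            if col in FIXED_COLUMNS or (col not in known):
                continue
            if col == TRANSFUSION_TOKEN:
                if raw == "":
                    continue
                try:
                    units = int(raw)
                except ValueError:
                    raise CohortParseError(
                        f"{path}:{row_number}: column {col!r}: "
                        f"{raw!r} is not an integer unit count"
                    ) from None
            elif col in flag_tokens:
                if raw in ("", "0"):
                    continue
                if raw != "1":
                    raise CohortParseError(
                        f"{path}:{row_number}: column {col!r}: flag value must be "
                        f"0/1/empty, got {raw!r}"
                    )
                flags.add(col)
            elif col in measurement_tokens:
                if raw == "":
                    continue
                try:
                    value = float(raw)
                except ValueError:
                    raise CohortParseError(
                        f"{path}:{row_number}: column {col!r}: {raw!r} is not numeric"
                    ) from None
                if col in unit_overrides:
                    value = value / UMOL_PER_L_DIVISORS[col]
                measurements[col] = value
        record = PatientRecord(
            record_id=data["record_id"],
            outcome=data.get("outcome", ""),
            timing=data.get("timing") or None,
            condition_category=frozenset(
                c for c in data.get("condition_category", "").split(";") if c
            ),
            flags=frozenset(flags),
            measurements=measurements,
            transfusion_units=units,
        )
        violations = validate_record(record, vocabulary)
        if violations:
            failures.append((row_number, record.record_id, violations))
        records.append(record)
    if failures:
        raise CohortValidationError(failures)
    return Cohort(records=records, live_births=live_births, label=label or path.stem)
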