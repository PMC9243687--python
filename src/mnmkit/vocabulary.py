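"""Controlled vocabulary of maternal near-miss indicator tokens.

Every criteria set evaluates against the same unified vocabulary of
condition flags, management flags, and laboratory/clinical measurements.
The shipped vocabulary is a versioned YAML document covering every token
referenced by any built-in criteria set; this is checked programmatically
when criteria are loaded.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

FLAG_KINDS = ("condition_flag", "management_flag")
MEASUREMENT_KIND = "measurement"
KINDS = FLAG_KINDS + (MEASUREMENT_KIND,)

#: Table-3-style condition groupings used for case-fatality reporting.
CONDITION_CATEGORIES = (
    "haemorrhage",
    "infection",
    "hypertensive",
    "medical",
    "labour_related",
)

TIMING_VALUES = (
    "antenatal_t1",
    "antenatal_t2",
    "antenatal_t3",
    "intrapartum",
    "postpartum",
    "post_abortion",
)

#: umol/L -> mg/dL divisors for the dual-unit analytes; thresholds are
#: stored canonically in mg/dL and conversions applied at ingest.
UMOL_PER_L_DIVISORS = {
    "creatinine_mg_dL": 88.4,
    "bilirubin_mg_dL": 17.1,
}


class VocabularyError(ValueError):
    """Raised when a vocabulary document violates its own invariants."""


@dataclass(frozen=True)
class IndicatorKey:
    """One controlled-vocabulary token.

    Parameters
    ----------
    name
        Unique token, e.g. ``platelet_count_per_mm3``.
    kind
        ``condition_flag``, ``management_flag`` or ``measurement``.
    unit
        Declared unit; required for measurements, forbidden for flags.
    label
        Human-readable description.
    """

    name: str
    kind: str
    unit: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise VocabularyError(f"unknown kind {self.kind!r} for token {self.name!r}")
        if self.kind == MEASUREMENT_KIND and not self.unit:
            raise VocabularyError(f"measurement token {self.name!r} must declare a unit")
        if self.kind in FLAG_KINDS and self.unit:
            raise VocabularyError(f"flag token {self.name!r} must not carry a unit")


class Vocabulary:
    """Immutable collection of :class:`IndicatorKey` with unique names."""

    def __init__(self, keys, version: str = "0"):
        self.version = version
        self._keys: dict[str, IndicatorKey] = {}
        for key in keys:
            if key.name in self._keys:
                raise VocabularyError(f"duplicate token {key.name!r}")
            self._keys[key.name] = key

    def __contains__(self, name: str) -> bool:
        return name in self._keys

    def __getitem__(self, name: str) -> IndicatorKey:
        return self._keys[name]

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self):
        return iter(self._keys.values())

    @property
    def flag_tokens(self) -> frozenset[str]:
        return frozenset(k.name for k in self if k.kind in FLAG_KINDS)

    @property
    def measurement_tokens(self) -> frozenset[str]:
        return frozenset(k.name for k in self if k.kind == MEASUREMENT_KIND)

    def kind_of(self, name: str) -> str:
        return self._keys[name].kind


def load_vocabulary(path: str | Path | None = None) -> Vocabulary:
    """Load a vocabulary YAML document; the shipped one by default."""
    if path is None:
        text = (resources.files("mnmkit") / "data" / "vocabulary.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    keys = [IndicatorKey(**entry) for entry in doc["tokens"]]
    return Vocabulary(keys, version=str(doc.get("version", "0")))


_DEFAULT: Vocabulary | None = None


def default_vocabulary() -> Vocabulary:
    """The shipped vocabulary, loaded once per process."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_vocabulary()
    return _DEFAULT
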