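{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/mnmkit/indicator-report.schema.json",
  "title": "IndicatorReport",
  "description": "Cohort-level counts and the four WHO near-miss process indicators for one criteria set. Full-precision values with presentation-rounded twins; an undefined MNM:MD ratio (no identified deaths) is serialized as null, never infinity.",
  "type": "object",
  "required": [
    "set_id", "n_near_miss", "n_deaths_identified", "n_deaths_missed",
    "n_smo", "live_births", "mnm_ratio_per_1000", "smo_ratio_per_1000",
    "mortality_index_pct", "mnm_to_md_ratio", "rounded"
  ],
  "properties": {
    "set_id": {"type": "string"},
    "n_near_miss": {"type": "integer", "minimum": 0},
    "n_deaths_identified": {"type": "integer", "minimum": 0},
    "n_deaths_missed": {"type": "integer", "minimum": 0},
    "n_smo": {"type": "integer", "minimum": 0},
    "live_births": {"type": "integer", "minimum": 1},
    "mnm_ratio_per_1000": {"type": "number", "minimum": 0},
    "smo_ratio_per_1000": {"type": "number", "minimum": 0},
    "mortality_index_pct": {"type": "number", "minimum": 0, "maximum": 100},
    "mnm_to_md_ratio": {"type": ["number", "null"], "minimum": 0},
    "rounded": {
      "type": "object",
      "required": [
        "mnm_ratio_per_1000", "smo_ratio_per_1000",
        "mortality_index_pct", "mnm_to_md_ratio"
      ],
      "properties": {
        "mnm_ratio_per_1000": {"type": "number"},
        "smo_ratio_per_1000": {"type": "number"},
        "mortality_index_pct": {"type": "number"},
        "mnm_to_md_ratio": {"type": ["number", "null"]}
      }
    }
  },
  "additionalProperties": false
}
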