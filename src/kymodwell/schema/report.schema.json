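{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "kymodwell pipeline report",
  "type": "object",
  "required": ["seed", "reference", "variants", "comparisons"],
  "properties": {
    "seed": {"type": "integer"},
    "reference": {"type": "string"},
    "variants": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": [
          "n_microtubules",
          "n_events",
          "n_end_events",
          "end_residence_mean_s",
          "end_residence_sem_s"
        ],
        "properties": {
          "n_microtubules": {"type": "integer"},
          "n_events": {"type": "integer"},
          "n_end_events": {"type": "integer"},
          "end_residence_mean_s": {"type": ["number", "null"]},
          "end_residence_sem_s": {"type": ["number", "null"]},
          "end_residence_corrected_mean_s": {"type": ["number", "null"]},
          "velocity_mean_nm_s": {"type": ["number", "null"]},
          "run_length_mean_um": {"type": ["number", "null"]}
        }
      }
    },
    "comparisons": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variant", "reference", "ks_D", "ks_p_value", "fold_change"],
        "properties": {
          "variant": {"type": "string"},
          "reference": {"type": "string"},
          "ks_D": {"type": "number"},
          "ks_p_value": {"type": "number"},
          "fold_change": {"type": ["number", "null"]},
          "fold_change_ci_low": {"type": ["number", "null"]},
          "fold_change_ci_high": {"type": ["number", "null"]}
        }
      }
    },
    "correlation_velocity_vs_end_residence": {
      "type": ["object", "null"],
      "required": ["r", "p_value", "n"],
      "properties": {
        "r": {"type": ["number", "null"]},
        "p_value": {"type": ["number", "null"]},
        "n": {"type": "integer"}
      }
    }
  }
}
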