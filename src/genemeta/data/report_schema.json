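{
  "type": "object",
  "required": ["metadata", "subjects", "maf", "hwe", "effects", "results", "bias", "sensitivity"],
  "properties": {
    "metadata": {
      "type": "object",
      "required": ["provenance", "package_version", "settings"],
      "properties": {
        "provenance": {"type": "string"},
        "package_version": {"type": "string"},
        "settings": {
          "type": "object",
          "required": ["models", "subgroup_keys", "het_threshold", "cc_increment"],
          "properties": {
            "models": {"type": "array", "items": {"type": "string"}},
            "subgroup_keys": {"type": "array", "items": {"type": "string"}},
            "het_threshold": {"type": "number"},
            "cc_increment": {"type": "number"}
          }
        }
      }
    },
    "subjects": {
      "type": "object",
      "required": ["cases", "controls_rows", "controls_unique"],
      "properties": {
        "cases": {"type": "integer"},
        "controls_rows": {"type": "integer"},
        "controls_unique": {"type": "integer"}
      }
    },
    "maf": {
      "type": "object",
      "required": ["case_t", "control_t_rows", "control_t_unique"],
      "properties": {
        "case_t": {"type": "number"},
        "control_t_rows": {"type": "number"},
        "control_t_unique": {"type": "number"}
      }
    },
    "hwe": {"type": "object"},
    "effects": {"type": "object"},
    "results": {"type": "object"},
    "bias": {"type": "object"},
    "sensitivity": {"type": "object"}
  }
}
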