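{
  "type": "object",
  "required_properties": {
    "metadata": {
      "type": "object",
      "required_properties": {
        "config_hash": {"type": "any"},
        "is_concentration_ng_ml": {"type": "number"},
        "n_analytes": {"type": "number"},
        "n_failed": {"type": "number"}
      }
    },
    "analytes": {
      "type": "object",
      "additional": {
        "type": "object",
        "required_properties": {
          "passed": {"type": "any"}
        }
      }
    }
  }
}
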