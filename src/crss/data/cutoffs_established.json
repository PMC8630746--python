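{
  "age": {"threshold": 65, "direction": "high_if_gt"},
  "albumin": {"threshold": 3.5, "direction": "high_if_le"},
  "b2m": {"threshold": 5.5, "direction": "high_if_ge"},
  "calcium": {"threshold": 11, "direction": "high_if_ge"},
  "egfr": {"threshold": 40, "direction": "high_if_le"},
  "hemoglobin": {"threshold": 10, "direction": "high_if_le"}
}
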