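{
  "age": {"threshold": 67, "direction": "high_if_gt"},
  "albumin": {"threshold": 3.5, "direction": "high_if_le"},
  "b2m": {"threshold": 4.78, "direction": "high_if_ge"},
  "calcium": {"threshold": 11, "direction": "high_if_ge"},
  "egfr": {"threshold": 48.2, "direction": "high_if_le"},
  "hemoglobin": {"threshold": 12.3, "direction": "high_if_le"}
}
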