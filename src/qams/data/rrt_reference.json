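{
  "reference_id": "loganin",
  "default_tolerance_percent": 5.0,
  "expected_rrt": {
    "gallic_acid": 0.16,
    "hmf": 0.22,
    "morroniside": 0.53,
    "cornin": 0.96,
    "sweroside": 0.98,
    "loganin": 1.0,
    "methylmorroniside_7a": 1.19,
    "methylmorroniside_7b": 1.20,
    "ethylmorroniside_7a": 1.46,
    "ethylmorroniside_7b": 1.48,
    "cornuside": 1.60
  }
}
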