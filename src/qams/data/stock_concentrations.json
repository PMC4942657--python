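{
  "gallic_acid": 124.44,
  "hmf": 120.12,
  "morroniside": 720.3,
  "cornin": 22.74,
  "sweroside": 60.66,
  "loganin": 415.2,
  "methylmorroniside_7a": 40.2,
  "methylmorroniside_7b": 81.52,
  "ethylmorroniside_7a": 20.16,
  "ethylmorroniside_7b": 20.12,
  "cornuside": 108.64
}
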