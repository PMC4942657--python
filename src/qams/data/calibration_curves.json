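{
  "gallic_acid": {"slope": 6411.2, "intercept": -13176.0, "r": 0.9999, "range": [3.89, 124.44]},
  "hmf": {"slope": 7856.0, "intercept": -7229.0, "r": 0.9999, "range": [3.75, 120.12]},
  "morroniside": {"slope": 14534.0, "intercept": -64815.0, "r": 0.9999, "range": [22.51, 720.30]},
  "cornin": {"slope": 10795.0, "intercept": -3398.3, "r": 0.9995, "range": [0.71, 22.74]},
  "sweroside": {"slope": 13446.0, "intercept": -7742.1, "r": 0.9998, "range": [1.90, 60.66]},
  "loganin": {"slope": 14317.0, "intercept": -32209.0, "r": 0.9999, "range": [12.97, 415.20]},
  "methylmorroniside_7a": {"slope": 12640.0, "intercept": -3224.1, "r": 0.9999, "range": [1.26, 40.20]},
  "methylmorroniside_7b": {"slope": 15128.0, "intercept": -9720.8, "r": 0.9998, "range": [2.55, 81.52]},
  "ethylmorroniside_7a": {"slope": 14273.0, "intercept": -283.77, "r": 0.9999, "range": [0.63, 20.16]},
  "ethylmorroniside_7b": {"slope": 12527.0, "intercept": -1411.6, "r": 0.9998, "range": [0.63, 20.12]},
  "cornuside": {"slope": 12461.0, "intercept": -11069.0, "r": 0.9999, "range": [3.39, 108.64]}
}
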