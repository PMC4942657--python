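compound_id,original_mg,added_mg,detected_mg,recovery_pct,rsd_pct
gallic_acid,0.030,0.031,0.064,108.15,1.18
hmf,0.033,0.033,0.068,105.29,1.48
morroniside,0.20,0.18,0.384,102.07,1.90
cornin,0.0017,0.0019,0.004,101.21,4.88
sweroside,0.016,0.017,0.034,108.73,1.55
loganin,0.12,0.114,0.239,104.27,0.42
methylmorroniside_7a,0.0059,0.0061,0.012,103.67,3.47
methylmorroniside_7b,0.0126,0.013,0.025,97.25,1.59
ethylmorroniside_7a,0.0049,0.0051,0.010,95.24,3.40
ethylmorroniside_7b,0.0053,0.0057,0.011,105.66,1.60
cornuside,0.025,0.024,0.049,98.54,0.64
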