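temperature_c,gallic_acid,hmf,morroniside,cornin,sweroside,methylmorroniside_7a,methylmorroniside_7b,ethylmorroniside_7a,ethylmorroniside_7b,cornuside
25,2.69,1.88,0.98,1.26,1.08,1.04,0.90,0.92,1.15,1.20
30,2.66,1.92,1.00,1.32,1.07,1.08,0.93,0.96,1.16,1.24
35,2.66,1.85,0.98,,,1.05,0.96,0.98,1.18,1.23
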