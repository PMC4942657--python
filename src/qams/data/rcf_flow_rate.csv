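flow_rate_ml_min,gallic_acid,hmf,morroniside,cornin,sweroside,methylmorroniside_7a,methylmorroniside_7b,ethylmorroniside_7a,ethylmorroniside_7b,cornuside
0.9,2.61,1.86,0.99,1.26,1.07,1.08,0.93,0.96,1.09,1.22
1.0,2.66,1.92,1.00,1.32,1.07,1.08,0.93,0.96,1.16,1.24
1.1,2.56,1.89,0.99,1.34,1.09,1.09,0.93,0.99,1.20,1.24
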