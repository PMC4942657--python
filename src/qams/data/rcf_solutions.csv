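solution,gallic_acid,hmf,morroniside,cornin,sweroside,methylmorroniside_7a,methylmorroniside_7b,ethylmorroniside_7a,ethylmorroniside_7b,cornuside
1,2.253,1.824,0.985,1.327,1.067,1.131,0.947,1.003,1.146,1.151
2,2.311,1.841,0.990,1.386,1.083,1.146,0.956,0.978,1.128,1.159
3,2.333,1.841,0.989,1.428,1.098,1.139,0.977,0.974,1.164,1.170
4,2.415,1.835,0.992,1.386,1.076,1.138,0.961,0.968,1.158,1.184
5,2.443,1.853,0.986,1.377,1.140,1.115,0.948,0.953,1.238,1.189
6,2.159,2.036,1.004,1.334,1.150,1.145,0.957,1.015,1.006,1.185
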