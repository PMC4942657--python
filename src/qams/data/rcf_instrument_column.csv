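instrument,column,gallic_acid,hmf,morroniside,cornin,sweroside,methylmorroniside_7a,methylmorroniside_7b,ethylmorroniside_7a,ethylmorroniside_7b,cornuside
Waters 2695-2998,Elite,2.44,1.87,0.99,1.37,1.10,1.14,0.96,0.98,1.15,1.17
Waters 2695-2998,Agilent,2.61,1.83,1.03,1.50,1.19,1.21,0.94,0.92,1.10,1.10
Waters 2695-2998,Wel Materials,2.68,1.85,0.99,1.44,1.18,1.18,0.87,0.94,1.07,1.10
Agilent 1100,Elite,2.66,1.65,0.98,1.52,1.04,1.12,0.95,0.95,1.03,1.10
Agilent 1100,Agilent,2.83,1.65,1.04,1.51,1.14,1.22,0.94,0.95,1.04,1.04
Agilent 1100,Wel Materials,2.65,1.73,0.95,1.47,1.14,1.13,0.91,0.93,1.05,1.02
Agilent 1260,Elite,2.74,1.75,1.06,1.52,1.19,1.26,0.98,0.94,1.14,1.15
Agilent 1260,Wel Materials,2.74,1.74,1.10,1.58,1.12,1.23,0.85,0.91,1.03,1.09
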