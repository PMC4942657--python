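instrument,column,gallic_acid,hmf,morroniside,cornin,sweroside,methylmorroniside_7a,methylmorroniside_7b,ethylmorroniside_7a,ethylmorroniside_7b,cornuside
Waters 2695-2998,Elite,0.16,0.21,0.51,0.95,0.97,1.19,1.20,1.46,1.47,1.59
Waters 2695-2998,Agilent,0.16,0.22,0.51,0.94,0.96,1.23,1.25,1.52,1.54,1.67
Waters 2695-2998,Wel Materials,0.16,0.22,0.57,0.97,0.98,1.17,1.19,1.43,1.46,1.58
Agilent 1100,Elite,0.16,0.21,0.52,0.96,0.98,1.18,1.19,1.45,1.46,1.59
Agilent 1100,Agilent,0.17,0.20,0.51,0.95,0.97,1.20,1.21,1.47,1.50,1.63
Agilent 1100,Wel Materials,0.16,0.24,0.57,0.97,0.99,1.16,1.19,1.43,1.45,1.58
Agilent 1260,Elite,0.16,0.22,0.53,0.96,0.98,1.18,1.20,1.46,1.47,1.60
Agilent 1260,Wel Materials,0.17,0.21,0.56,0.97,0.99,1.17,1.19,1.44,1.46,1.58
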