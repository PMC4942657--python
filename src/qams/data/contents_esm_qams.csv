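sample_id,sample_type,loganin_esm,gallic_acid_esm,gallic_acid_qams,hmf_esm,hmf_qams,morroniside_esm,morroniside_qams,cornin_esm,cornin_qams,sweroside_esm,sweroside_qams,methylmorroniside_7a_esm,methylmorroniside_7a_qams,methylmorroniside_7b_esm,methylmorroniside_7b_qams,ethylmorroniside_7a_esm,ethylmorroniside_7a_qams,ethylmorroniside_7b_esm,ethylmorroniside_7b_qams,cornuside_esm,cornuside_qams
1,crude,7.32,0.50,0.54,,,8.22,8.25,0.26,0.27,0.87,0.90,0.02,0.02,0.07,0.07,,,,,1.30,1.32
2,crude,7.45,0.39,0.41,,,5.53,5.52,0.25,0.27,0.90,0.92,0.01,0.01,0.05,0.04,,,,,1.28,1.31
3,crude,7.30,0.53,0.58,,,6.28,6.29,0.26,0.28,0.87,0.90,0.01,0.01,0.08,0.08,,,,,1.26,1.28
4,crude,6.94,0.45,0.49,,,5.35,5.34,0.19,0.19,0.66,0.67,0.01,0.01,0.05,0.04,,,,,1.17,1.19
5,crude,7.11,0.67,0.73,,,4.85,4.84,0.20,0.21,0.73,0.75,0.03,0.03,0.08,0.07,,,,,1.23,1.25
6,crude,7.78,0.45,0.48,,,6.49,6.50,0.22,0.23,0.78,0.80,0.02,0.01,0.06,0.05,,,,,1.65,1.68
7,crude,7.54,0.43,0.46,,,10.65,10.70,0.25,0.26,0.83,0.85,0.02,0.01,0.07,0.07,,,,,1.65,1.68
8,crude,7.38,0.41,0.44,,,6.37,6.37,0.27,0.28,0.74,0.76,0.01,0.01,0.07,0.06,,,,,1.66,1.69
9,crude,6.86,0.42,0.45,,,8.85,8.88,0.24,0.25,0.87,0.90,0.01,0.01,0.05,0.05,,,,,1.55,1.58
10,crude,7.60,0.40,0.43,,,7.85,7.87,0.26,0.27,0.92,0.95,0.01,0.01,0.04,0.04,,,,,1.74,1.77
11,crude,6.22,0.50,0.54,,,7.88,7.91,0.27,0.28,0.86,0.88,0.01,0.01,0.06,0.06,,,,,0.96,0.97
12,crude,7.64,0.54,0.59,,,4.79,4.78,0.20,0.21,0.80,0.83,0.01,0.01,0.05,0.04,,,,,1.20,1.22
13,crude,7.13,0.45,0.49,,,3.50,3.48,0.18,0.19,0.72,0.74,0.01,0.01,0.04,0.03,,,,,1.01,1.03
14,crude,6.89,1.15,1.28,,,7.30,7.32,0.28,0.30,0.93,0.96,0.01,0.01,0.07,0.06,,,,,1.04,1.05
15,crude,6.47,1.10,1.23,,,7.77,7.79,0.27,0.28,0.86,0.88,0.01,0.01,0.06,0.06,,,,,1.00,1.01
16,crude,6.87,0.96,1.07,,,10.41,10.46,0.28,0.30,0.89,0.92,0.01,0.01,0.07,0.06,,,,,1.10,1.12
17,crude,6.28,1.07,1.20,,,7.49,7.51,0.28,0.29,0.86,0.89,0.02,0.02,0.06,0.06,,,,,0.98,1.00
18,crude,6.26,1.06,1.19,,,7.89,7.91,0.27,0.28,0.86,0.89,0.01,0.01,0.06,0.06,,,,,0.95,0.96
19,crude,6.58,1.39,1.56,,,6.96,6.97,0.27,0.29,0.97,1.00,0.01,0.01,0.07,0.06,,,,,0.98,0.99
20,crude,6.26,1.13,1.26,,,6.52,6.53,0.27,0.29,0.86,0.88,0.02,0.02,0.06,0.05,,,,,0.95,0.96
21,crude,7.01,1.27,1.42,,,8.04,8.07,0.29,0.30,0.91,0.94,0.02,0.02,0.07,0.07,,,,,1.03,1.04
22,processed,6.63,2.15,2.43,1.67,1.71,9.41,9.45,0.29,0.30,0.95,0.98,0.01,0.01,0.07,0.07,0.14,0.14,0.23,0.23,0.81,0.82
23,processed,6.49,2.10,2.38,2.07,2.12,10.21,10.26,0.28,0.30,0.96,0.99,0.02,0.02,0.07,0.06,0.15,0.15,0.25,0.25,0.86,0.87
24,processed,7.92,2.40,2.72,1.42,1.45,13.52,13.59,0.34,0.36,1.10,1.14,0.02,0.02,0.09,0.08,0.20,0.19,0.30,0.30,1.10,1.12
25,processed,6.86,1.28,1.44,1.81,1.86,8.76,8.79,0.22,0.23,0.76,0.78,0.01,0.01,0.05,0.05,0.24,0.24,0.28,0.28,1.11,1.12
26,processed,7.95,1.30,1.46,2.04,2.10,11.32,11.37,0.25,0.26,0.87,0.90,0.01,0.01,0.05,0.04,0.24,0.24,0.27,0.27,1.27,1.28
27,processed,6.28,1.97,2.23,1.91,1.96,9.57,9.62,0.28,0.30,0.85,0.87,0.03,0.03,0.09,0.08,0.24,0.24,0.27,0.27,0.87,0.88
28,processed,6.60,2.01,2.27,1.94,1.99,10.88,10.94,0.30,0.31,0.91,0.94,0.01,0.01,0.06,0.06,0.24,0.23,0.28,0.28,0.94,0.95
29,processed,6.44,2.11,2.39,1.66,1.70,10.97,11.03,0.27,0.29,0.81,0.83,0.02,0.02,0.08,0.07,0.23,0.22,0.24,0.24,0.94,0.95
30,processed,6.67,2.01,2.27,1.71,1.75,11.45,11.51,0.29,0.31,0.77,0.79,0.02,0.02,0.07,0.07,0.20,0.19,0.23,0.22,0.96,0.97
31,processed,8.63,1.34,1.50,2.43,2.49,14.02,14.09,0.31,0.32,0.89,0.92,0.02,0.02,0.09,0.09,0.35,0.34,0.38,0.38,1.75,1.78
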