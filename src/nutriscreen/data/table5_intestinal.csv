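code,Biuret_I,DirectDetect_I,FreeNH2_I,ABTS_I,FRAP_I,DPPH_I,ORAC_I
A1,496,839,6199,15.71,3.99,44.64,0.15
A2,250,670,3418,26.62,5.11,48.87,0.46
A3,551,733,2454,30.16,7.00,51.30,0.03
A4,461,859,2642,18.28,4.66,53.44,1.26
A5,271,660,3257,51.42,17.45,65.20,0.05
A6,187,739,3791,70.33,26.11,66.89,0.10
A7,549,546,1661,21.02,6.73,56.00,0.40
A8,418,1213,2362,35.20,10.55,33.00,0.10
A9,341,870,5142,43.77,10.47,59.93,0.17
D1,763,333,798,5.76,5.13,25.65,0.02
D2,568,464,2559,16.17,5.91,33.16,0.12
D3,335,530,2188,14.37,4.59,20.82,0.06
D4,525,604,2486,18.33,13.80,44.11,0.11
D5,563,837,3529,14.38,2.14,34.96,0.13
D6,505,854,3433,11.26,2.25,35.49,0.07
D7,412,861,5146,10.89,2.03,24.96,0.04
D8,452,786,3004,13.21,2.87,31.98,0.19
D9,507,819,4205,16.58,4.45,44.03,0.17
P1,144,253,1000,80.10,38.49,76.62,0.09
P2,186,771,650,67.21,43.21,71.85,0.17
P3,325,586,2511,74.90,22.60,38.91,0.13
P4,541,719,2158,25.30,6.46,45.33,0.22
P5,502,554,3264,22.16,6.04,39.38,0.14
P6,418,423,3059,28.80,13.33,21.81,0.51
P7,463,506,4968,35.26,13.85,47.83,0.36
P8,310,808,2372,39.08,22.60,39.84,0.08
P9,300,628,2403,82.56,82.78,66.40,0.06
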