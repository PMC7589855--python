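code,Biuret_G,DirectDetect_G,FreeNH2_G,ABTS_G,FRAP_G,DPPH_G,ORAC_G
A1,546,541,4317,26.358,5.31,51.57,0.11
A2,478,435,1858,37.99,6.09,47.59,0.16
A3,558,215,191,25.23,5.63,16.72,1.13
A4,516,568,1794,30.98,6.27,60.97,0.34
A5,364,407,2285,77.63,15,72.41,0.09
A6,269,459,2152,94.66,39.83,79.45,0.06
A7,1064,276,334,24.79,5.97,9.15,0.90
A8,536,663,1942,60.39,16.66,44.6,0.06
A9,370,571,3458,73.82,16.41,62.08,0.06
D1,800,153,208,15.57,4.24,54.22,0.29
D2,722,231,938,15.8,5.35,21.72,0.3
D3,483,211,231,18.36,4.49,57.87,0.14
D4,901,246,569,15.1,6.38,52.89,0.31
D5,1018,262,393,11.45,0.99,48.16,0.6
D6,839,298,318,12.84,2.11,63.68,0.27
D7,462,324,506,10.78,1.69,56.53,0.24
D8,698,278,367,12.68,1.95,63.67,1.02
D9,869,390,967,14.13,3.60,49.25,0.38
P1,219,94,438,88.71,42.90,75.49,0.02
P2,203,382,408,88.84,43.06,71.11,0.11
P3,431,246,534,47.63,11.14,22.01,0.29
P4,859,334,464,20.95,3.86,44.86,0.29
P5,874,187,406,14.61,2.36,41.79,0.32
P6,675,140,367,21.86,9.73,9.61,1.60
P7,628,170,645,21.69,9.33,31.04,0.17
P8,295,261,289,39.63,29.04,32.18,0.26
P9,505,235,608,82.09,15.51,38.15,0.08
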