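code,DM,Protein,TotalSugar,SimpleCarb,ComplexCarb,Cr,Cu,Zn,Fe,Na,Mg,K,Ca,VitC,VitA,TBARS,Carbonyls,His,Ile,Leu,Lys,Met,Phe,Thr,Trp,Val,Arg,Ala,Asp,Cys,Glu,Gly,Pro,Ser,Tyr,IAA_TotalAA,TotalAA
A1,96.79,83.46,0.85,1.12,n.r.,0.28,2.69,26.58,34.96,12142,194,1444,549,1.35,151.93,0.50,17.24,1.85,3.30,6.24,6.02,0.70,3.32,3.76,0.96,4.21,5.23,6.09,7.28,0.52,11.89,11.52,6.02,3.27,2.01,36.1,84.18
A2,94.39,66.10,1.11,0.74,0.37,0.12,0.12,1.84,4.14,5892,428,6584,600,0.99,n.r.,12.40,7.11,2.31,3.38,7.32,5.43,0.66,3.26,3.73,0.82,4.24,2.56,5.50,5.78,0.47,12.65,4.37,4.19,1.81,1.35,44.6,69.83
A3,95.98,85.38,0.53,1.05,n.r.,0.13,2.26,34.02,29.74,1254,203,1065,1544,1.28,n.r.,1.26,14.99,1.99,3.23,6.48,6.08,0.31,3.50,3.80,0.87,4.60,5.12,6.52,7.29,0.40,11.06,11.02,7.42,3.23,2.05,36.3,84.98
A4,97.10,88.60,0.51,0.84,n.r.,1.99,0.74,3.56,17.60,18848,592,6796,569,1.25,n.r.,0.33,16.69,2.22,1.54,3.54,4.20,0.13,2.15,2.14,0.11,2.73,6.14,8.31,6.07,0.16,11.48,20.90,11.52,3.24,0.86,21.5,87.46
A5,91.46,66.50,0.95,1.17,n.r.,0.49,27.83,202.21,619.75,8523,541,5955,251,0.17,374.76,22.21,23.32,1.63,3.77,7.19,5.88,0.62,3.85,3.62,1.81,4.73,0.89,4.52,6.57,0.57,9.86,4.72,4.31,3.02,0.99,48.3,68.55
A6,92.91,65.85,1.70,0.97,0.74,0.01,0.18,0.06,0.13,6,4,9,3,0.58,381.00,3.36,8.57,1.68,4.09,7.98,2.28,0.84,4.02,2.88,1.26,5.25,1.55,5.02,7.09,0.52,9.89,4.82,3.88,2.25,1.45,45.4,66.74
A7,96.31,61.13,0.42,1.56,n.r.,0.40,0.23,39.19,103.33,2311,535,3193,6521,0.84,88.89,2.23,15.57,1.83,3.12,5.77,5.52,0.20,2.90,3.37,0.84,3.31,3.65,4.51,6.15,0.15,9.90,6.28,3.99,2.65,2.11,40.5,66.26
A8,95.83,88.19,0.86,0.31,0.54,1.80,6.72,40.44,201.35,13140,762,39808,331,0.77,n.r.,1.24,10.63,1.83,2.73,5.54,5.25,0.49,2.87,3.93,0.35,3.42,5.96,7.12,6.77,0.36,12.14,14.41,7.85,3.06,1.95,30.7,86.02
A9,94.16,88.54,0.48,0.40,0.09,0.24,0.01,6.18,9.20,9539,963,8542,306,0.67,n.r.,0.36,6.76,3.20,3.68,6.77,6.89,0.61,3.64,4.27,0.56,3.88,4.08,7.22,7.96,0.97,14.25,11.03,5.25,3.19,2.49,37.2,89.95
D1,97.82,28.19,9.28,1.91,7.37,0.27,0.50,23.27,9.68,5850,293,3510,7583,0.36,n.r.,0.22,1.87,0.95,1.60,2.90,2.21,0.42,1.58,1.24,0.62,1.80,0.92,0.97,2.06,0.85,6.20,0.56,3.42,1.47,1.50,42.6,31.26
D2,92.79,64.50,1.61,1.11,0.50,0.41,2.14,1.67,6.89,21713,68,248,698,0.71,n.r.,n.r.,8.38,1.12,6.18,5.72,5.99,0.22,1.55,7.25,0.66,5.68,2.72,5.72,9.89,0.51,20.36,1.08,10.98,5.52,1.09,37.3,92.24
D3,95.62,49.96,20.82,2.23,18.60,0.63,0.74,50.78,5.51,1485,653,6233,16313,0.20,n.r.,0.01,2.82,1.26,1.52,4.51,5.87,0.66,2.36,2.31,0.95,1.89,2.79,1.52,4.11,0.92,11.23,1.77,11.89,2.22,1.72,35.8,59.50
D4,95.55,76.19,1.89,0.29,1.61,0.08,2.72,2.32,19.04,2426,518,4825,3197,0.66,n.r.,0.48,9.21,1.27,4.89,9.04,8.82,0.61,2.33,5.62,1.51,4.62,1.68,4.30,5.13,0.97,14.08,1.45,4.23,3.35,1.75,51.2,75.65
D5,95.57,85.42,0.54,0.32,0.23,0.11,0.25,0.39,10.71,542,396,527,1564,1.14,n.r.,0.30,11.47,1.65,5.59,9.85,7.73,1.24,2.96,6.34,0.24,5.03,1.86,4.51,8.83,0.47,15.16,1.59,5.20,3.89,2.00,48.3,84.13
D6,95.59,91.13,0.18,0.30,n.r.,0.06,0.13,20.82,12.76,49,61,44,7587,0.46,n.r.,n.r.,4.53,2.76,4.40,9.05,7.15,1.34,4.85,3.86,0.20,5.63,2.51,2.74,6.30,0.37,20.10,1.61,8.99,4.95,3.85,43.3,90.65
D7,88.81,81.69,0.06,0.04,0.03,0.14,0.15,76.52,5.37,52,648,122,17782,1.05,n.r.,n.r.,2.65,2.53,3.59,8.67,6.69,1.58,4.55,3.30,0.59,4.87,2.32,2.28,6.06,0.33,19.38,1.57,8.99,4.93,4.25,42.0,86.47
D8,93.77,81.63,1.21,1.47,n.r.,0.27,0.15,66.29,14.57,6368,484,1336,11730,0.48,n.r.,n.r.,5.37,2.40,4.26,8.53,6.67,1.61,4.08,3.91,1.17,5.19,1.51,2.71,6.24,0.67,17.94,1.46,7.96,4.38,3.36,45.0,84.05
D9,95.34,77.75,2.30,1.01,1.29,0.12,12.11,77.71,104.30,3511,5026,4740,3471,1.28,n.r.,0.20,4.71,1.61,5.35,9.26,7.74,0.72,2.76,6.44,1.68,4.87,1.52,4.26,9.19,0.98,14.94,1.49,4.69,3.86,2.20,48.4,83.56
P1,39.05,26.15,9.46,1.08,8.39,0.11,8.13,25.39,26.38,102,661,4362,236,1.02,3.45,1.47,11.63,0.98,1.38,2.37,1.89,0.48,1.38,1.09,0.11,1.35,2.46,1.23,2.46,0.62,4.66,1.30,1.59,1.62,1.02,39.4,27.98
P2,43.07,24.69,7.05,2.78,4.28,0.02,6.29,23.06,22.64,6,579,4448,190,1.48,4.73,0.57,5.67,0.89,1.55,3.05,2.05,0.38,1.51,1.11,0.12,1.65,1.15,1.28,2.66,0.52,4.89,1.25,1.59,1.56,1.18,43.3,28.38
P3,92.68,49.13,12.31,2.58,9.74,0.53,16.45,92.09,173.13,2,5733,5894,1463,0.69,3.04,7.33,5.71,1.40,1.85,3.55,2.09,0.64,2.49,2.24,0.61,5.59,4.50,2.49,5.65,0.59,9.95,2.49,2.52,2.68,1.86,38.4,53.19
P4,94.21,84.79,2.70,1.32,1.38,0.17,7.81,49.29,125.85,6322,471,1744,706,0.85,2.10,2.14,7.22,1.98,5.71,9.83,7.86,0.24,2.89,6.14,0.77,5.32,1.98,4.52,8.89,0.55,14.89,1.52,5.18,3.68,1.89,48.6,83.84
P5,94.01,69.89,1.81,1.39,0.42,0.38,10.44,61.54,140.11,4815,405,2183,563,1.71,0.41,1.14,7.45,1.98,2.72,7.02,8.89,0.51,4.23,3.42,0.88,3.25,6.42,3.55,10.25,0.45,16.72,3.42,8.12,4.52,2.55,37.0,88.90
P6,92.89,58.61,11.65,0.52,11.14,0.61,5.49,24.12,89.71,68,1665,5423,1598,1.03,0.17,0.24,4.96,1.78,2.19,5.42,7.42,0.61,3.52,3.12,0.72,2.31,4.89,3.15,9.15,0.42,15.62,2.78,8.13,3.55,2.25,35.2,77.03
P7,96.24,76.35,1.71,0.67,1.05,0.34,10.10,23.00,97.34,3150,180,4905,405,1.24,0.50,1.65,7.45,2.42,3.56,8.12,6.85,0.52,5.52,4.52,0.75,3.99,7.05,4.36,9.22,0.48,20.12,4.22,9.12,5.21,2.63,36.7,98.66
P8,95.63,57.81,9.07,1.02,8.05,0.15,13.54,87.02,114.47,3924,5377,5945,690,0.85,6.19,3.24,10.51,1.37,2.32,4.76,2.30,0.49,3.52,2.36,0.91,2.89,6.08,2.98,6.01,0.42,12.50,3.61,2.50,3.19,2.14,34.7,60.35
P9,91.07,54.77,12.80,1.47,11.33,0.24,28.86,90.54,85.49,33,4680,5753,1494,1.37,0.66,0.36,3.79,1.64,2.45,4.05,2.06,0.58,3.02,2.65,0.87,3.00,6.52,2.45,5.65,0.59,13.25,3.42,3.06,2.51,1.68,34.2,59.45
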