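latent,var_set,k,members,high,medium,low
Peptides_G,gastric,2,DirectDetect_G;FreeNH2_G,A1;A3;A5;A6;A7;A8;A9,,A2;A4;D1;D2;D3;D4;D5;D6;D7;D8;D9;P1;P2;P3;P4;P5;P6;P7;P8;P9
Antiox_G,gastric,2,ABTS_G;FRAP_G;DPPH_G,A5;A7;A8;A9;P2;P3;P4;P9,,A1;A2;A3;A4;A6;D1;D2;D3;D4;D5;D6;D7;D8;D9;P1;P5;P6;P7;P8
BiuretORAC_G,gastric,3,Biuret_G;ORAC_G,A2;A4;D1;D2;D3;D5;D8;D9;P1;P7;P8,A7;A8;A9;P2;P3;P4,A1;A3;A5;A6;D4;D6;D7;P5;P6;P9
Peptides_I,intestinal,3,DirectDetect_I;FreeNH2_I,A1;A4;A6;A8;A9;D5;D6;D7;D8;D9,A2;A3;A5;D2;D3;D4;P3;P4;P5;P6;P7;P8;P9,A7;D1;P1;P2
Antiox_I,intestinal,3,ABTS_I;FRAP_I;DPPH_I,A6;P1;P2;P9,A1;A2;A3;A4;A5;A7;A9;D4;D9;P3;P4;P7;P8,A8;D1;D2;D3;D5;D6;D7;D8;P5;P6
BiuretORAC_I,intestinal,2,Biuret_I;ORAC_I,A1;A3;A4;A7;D1;D2;D4;D5;D6;D8;D9;P4;P5;P6;P7,,A2;A5;A6;A8;A9;D3;D7;P1;P2;P3;P8;P9
Prot_HFDSEP,composition,2,Protein;His;Phe;Asp;Ser;Glu;Pro,A1;A3;A4;A8;A9;D2;D5;D6;D7;D8;D9;P4;P5;P6;P7,,A2;A5;A6;A7;D1;D3;D4;P1;P2;P3;P8;P9
TIVLK,composition,3,Thr;Ile;Val;Leu;Lys,D2;D5;D4;D9;P4,A4;D1;D3;P1;P2;P3;P8;P9,A1;A2;A3;A5;A6;A7;A8;A9;D6;D7;D8;P5;P6;P7
Ca_YM,composition,2,Ca;Tyr;Met,D3;D6;D7;D8,,A1;A2;A3;A4;A5;A6;A7;A8;A9;D1;D2;D4;D5;D9;P1;P2;P3;P4;P5;P6;P7;P8;P9
Carbohydrates_Mg,composition,2,TotalSugar;ComplexCarb;SimpleCarb;Mg,D1;D3;P1;P2;P3;P6;P8;P9,,A1;A2;A3;A4;A5;A6;A7;A8;A9;D2;D4;D5;D6;D7;D8;D9;P4;P5;P7
Micro-nutrients,composition,2,Cu;Zn;Fe,A5;D1;D9;P3;P5;P8;P9,,A1;A2;A3;A4;A6;A7;A8;A9;D2;D3;D4;D5;D6;D7;D8;P1;P2;P4;P6;P7
VitA_Ox,composition,2,VitA;TBARS;Carbonyls,A5;A6,,A1;A2;A3;A4;A7;A8;A9;D1;D2;D3;D4;D5;D6;D7;D8;D9;P1;P2;P3;P4;P5;P6;P7;P8;P9
C and W,composition,3,Cys;Trp,A9;D1;D3;D4;D9,A4;A8;D5;D6;D7;P1;P2,A1;A2;A3;A5;A6;A7;D2;D8;P3;P4;P5;P6;P7;P8;P9
CrKNa_GA,composition,2,Cr;K;Na;Gly;Ala,A4;A8,,A1;A2;A3;A5;A6;A7;A9;D1;D2;D3;D4;D5;D6;D7;D8;D9;P1;P2;P3;P4;P5;P6;P7;P8;P9
VitC_R,composition,2,VitC;Arg,A1;A2;A3;A4;A7;A8;D5;D7;D9;P1;P2;P3;P5;P6;P7;P8;P9,,A5;A6;A9;D1;D2;D3;D4;D6;D8;P4
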