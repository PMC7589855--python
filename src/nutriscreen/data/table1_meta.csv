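code,origin,description
A1,animal,Pork meat broth (hydrolyzed)
A2,animal,Pork heart
A3,animal,Pork broth
A4,animal,Pork collagen
A5,animal,Pork liver
A6,animal,Pork liver
A7,animal,Chicken broth
A8,animal,Chicken collagen
A9,animal,Chicken meat
D1,dairy,Cheese powder
D2,dairy,80% serum protein concentrate
D3,dairy,60% micellar casein concentrate
D4,dairy,Whey protein
D5,dairy,Whey protein
D6,dairy,Calcium caseinate
D7,dairy,Casein rennet
D8,dairy,Milk protein concentrate
D9,dairy,Whey protein
P1,plant,Fava bean
P2,plant,Fava bean (fermented)
P3,plant,Hemp
P4,plant,Pea
P5,plant,Pea
P6,plant,Soybean
P7,plant,Soybean
P8,plant,Pumpkinseed
P9,plant,Sunflower
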