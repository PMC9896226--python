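drug,pubs_MND,pubs_AD,pubs_HD,pubs_MS,pubs_PD,pubs_total,participants_MND,participants_AD,participants_HD,participants_MS,participants_PD,participants_total
Acetyl-L-carnitine,0,9,1,0,0,10,0,1224,10,0,0,1234
Ciclosporin,2,0,0,7,0,9,110,0,0,1092,0,1202
Fluoxetine,0,0,1,2,3,6,0,0,30,51,32,113
Melatonin,1,4,0,0,3,8,3,273,0,0,64,340
Memantine,1,32,2,1,15,51,63,11912,39,116,809,12939
N-acetyl cysteine,0,1,0,0,0,1,0,47,0,0,0,47
Simvastatin,0,3,0,1,1,5,0,469,0,307,12,788
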