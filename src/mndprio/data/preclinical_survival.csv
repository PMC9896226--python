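publication,drug,n_animals,median_survival_treated,median_survival_control,logmsr
Kira 2006,Acetyl-L-carnitine,20,270,240,0.1178
Barneoud 1999,Aspirin,38,150,155,-0.0328
Tanaka 2011,Bromocriptine,69,40,35,0.1335
Drachman 2002,Celecoxib,55,139,119,0.1554
Karlsson 2004,Ciclosporin,13,144,130,0.1023
Keep 2001,Ciclosporin,11,24,12,0.6931
Turner 2003,Clozapine,16,140,132,0.0588
Andreassen 2001,Creatine,24,155,135,0.1382
Kaddurah-Daouk 2000,Creatine,13,169,144,0.1601
Klivenyi 2004,Creatine,22,150,125,0.1823
Choi 2008,Oestrogen,70,135,127,0.0611
Koschnitzky 2014,Fluoxetine,34,139,132,0.0517
Gurney 1996,Gabapentin,17,140,139,0.0072
Gurney 1996b,Gabapentin,38,175,165,0.0588
Ferrante 2001,Ginkgo biloba,20,136,125,0.0843
Fornai 2008,Lithium,20,146,117,0.2214
Gill 2009,Lithium,55,124,127,-0.0239
Pizzasegola 2009,Lithium,20,119,129,-0.0807
Dardiotis 2013,Melatonin,28,143,143,0.0000
Weishaupt 2006,Melatonin,50,137,131,0.0448
Zhang 2013,Melatonin,30,145,137,0.0568
Wang 2005,Memantine,21,130,122,0.0635
Keller 2011,Minocycline,32,147,138,0.0632
Kriz 2002,Minocycline,29,364,336,0.0800
Van Den Bosch 2002,Minocycline,14,155,130,0.1759
Zhang 2003,Minocycline,20,140,130,0.0741
Zhu 2002,Minocycline,20,135,127,0.0611
Andreassen 2000,N-acetyl cysteine,30,134,129,0.0380
Jaarsma 1998,N-acetyl cysteine,28,251,239,0.0490
Yip 2013,Omega 3,32,182,182,0.0000
Petri 2006,Sodium phenylbutyrate,26,139,127,0.0903
Ryu 2005,Sodium phenylbutyrate,40,145,127,0.1325
Crochemore 2009,Valproate,11,140,140,0.0000
Rouaux 2007,Valproate,36,115,110,0.0445
Sugai 2004,Valproate,17,295,265,0.1072
Gianfocaro 2013,Vitamin D,100,126,124,0.0160
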