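intervention,n_publications,quality,efficacy,safety,study_size,drug_score
Rivastigmine,29,3.34,3.33,2.1,2.62,90.62
Memantine,51,3.02,2.87,2.2,2.47,80.7
Vitamin D3,11,3.27,3.01,3.36,2.18,78.08
Donepezil,41,3.1,2.72,2.51,2.24,76.99
Pramipexole,14,3.07,3.04,2.43,2.64,70.41
Galantamine,12,2.75,2.85,2.67,2.5,58.29
Amantadine,59,2.37,3,2.36,1.9,56.53
Dextromethorphan/quinidine,3,4,3.33,2.33,3,56.19
Selegiline,21,3,2.59,2.1,2.38,51.98
4-aminopyridine,10,3.2,2.76,2.5,2.1,48.28
Acetyl-L-carnitine,10,2.9,2.64,2.5,2.3,45.83
Simvastatin,5,3.6,2.27,2.8,2.4,42.73
Lamotrigine,6,4,2.25,2.33,2.33,41.41
Bromocriptine,13,2.92,2.4,2.54,1.92,39.21
Clozapine,6,3,2.9,2.5,2,36.8
Gabapentin,9,2.67,2.4,2.44,2.33,36.46
Creatine,12,2.67,2.14,2.33,2.42,35.87
Ginkgo biloba,3,3.67,2.61,3.67,1.67,35.21
Minocycline,11,2.45,2.27,2.64,2.18,34.54
Vitamin E,9,3.33,2.1,2,2.44,34.25
Levetiracetam,6,3,3.33,2.17,1.83,33.57
Atomoxetine,4,3.25,2.5,3.25,1.75,32.3
Coenzyme Q10,9,3.33,2.16,1.89,2.33,31.67
Tacrine,10,3.3,2.81,1.8,1.8,31.26
Olanzapine,5,2.4,3.47,2.6,1.6,26.93
Oestrogen,9,3,2.66,1.67,2,26.57
Nimodipine,5,3,2.35,2.2,2.2,26.55
Riluzole,17,2.41,2.35,1.76,2.06,25.88
Ciclosporin,9,2.78,1.93,2.11,2.22,25.15
Dextromethorphan,7,2.29,2.4,2.71,1.86,24.97
Naltrexone,8,2.5,2.22,2.62,1.75,24.29
Theophylline,2,4,3.25,2.5,1.5,23.26
Valproate,9,2.56,2.33,2,1.89,22.53
Fluoxetine,6,2.67,2.42,2.33,1.67,21.18
Levamisole,3,2.67,2.78,2.33,2,20.81
Melatonin,8,2,2.11,2.75,1.88,20.81
Celecoxib,2,4,2,1.5,3,17.18
"3,4-diaminopyridine",6,2.83,2.4,2.17,1.33,16.62
Milacemide,4,3,1.75,2.25,2,16.51
N-acetyl cystine,1,3,3,3,2,16.26
Tranylcypromine,2,2.5,2.5,3.5,1.5,15.66
Aspirin,4,2.75,2,1.75,2.25,15.14
Ursodeoxycholic acid,1,4,2,3,2,14.45
Tolbutamide,2,3,2.5,2,2,14.31
Imipramine,2,3.5,2,2,2,13.36
Lithium,12,2.42,2.19,1.5,1.5,13.29
Modafinil,2,4,3.33,1,2,12.72
Omega 3 fatty acid,2,2.5,1.75,3,2,12.52
Octacosanol,2,2.5,2,3.5,1.5,12.52
Indinavir,2,3.5,1.8,1.5,2.5,11.27
Sodium phenylbutyrate,1,4,2,2,2,9.63
Tilorone,1,4,2,2,2,9.63
lipoic acid,2,2.5,2,2,2,9.54
Isoprinosine,4,3,1.75,1.25,2,9.17
Tetrahydrocannabinol,2,3.5,1.5,1.5,2,7.51
Topiramate,1,4,1,2,3,7.22
Haloperidol,2,3,2.33,1,1.5,5.01
Amino acid mixture,5,1.6,2,1,2,4.98
Rolipram,2,1.5,2,3,1,4.29
Alsamin,1,2,3.5,1,2,4.21
Pentoxifylline,3,2,1.61,1,2,3.88
Verapamil,1,2,2,1,2,2.41
IGF-1,1,2,1,1,3,1.81
Propranolol,1,1,3,1,2,1.81
Fluvoxamine,2,1,3,1,1,1.43
Amitriptyline,1,1,1,3,1,0.9
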