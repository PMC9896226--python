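drug,round,reason
Bromocriptine,1,Unfavourable safety profile
Gabapentin,1,>3 previous clinical trials in MND
Creatine,1,>3 previous clinical trials in MND
Clozapine,1,Unfavourable safety profile
Minocycline,1,>3 previous clinical trials in MND
Valproate,1,>3 previous clinical trials in MND
Celecoxib,1,Unfavourable safety profile
Aspirin,1,Poor biological plausibility
Ginkgo biloba,1,Poor biological plausibility
Lithium,1,>3 previous clinical trials in MND
Amino acid mixture,1,>3 previous clinical trials in MND
Oestrogen,2,Aggregate judgement of data presented
Vitamin D3,2,Aggregate judgement of data presented
Omega 3,2,Aggregate judgement of data presented
Sodium phenylbutyrate,2,Aggregate judgement of data presented
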