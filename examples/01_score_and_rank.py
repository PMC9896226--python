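"""Score a tiny clinical corpus and rank its drugs.

Builds two drugs' worth of publications in memory, scores each publication
on safety, efficacy, quality and study size, and aggregates into the
ranked drug score: product of the four per-drug domain means times
log10(1 + number of publications).
"""

from mndprio import rank_corpus, score_corpus
from mndprio.records import Corpus, OutcomeRecord, PublicationRecord, QualityResponse

corpus = Corpus.from_records(
    publications=[
        PublicationRecord("p1", "Memantine", "MND", 2010, "rct", 63, "ae_only", "p1_o1"),
        PublicationRecord("p2", "Memantine", "AD", 2008, "rct", 250, "none_reported", None),
        PublicationRecord("p3", "Riluzole", "MND", 1996, "rct", 959, "sae_only", "p3_o1"),
    ],
    outcomes=[
        OutcomeRecord("p1", "p1_o1", "neutral"),
        OutcomeRecord("p2", "p2_o1", "significant_improvement"),
        OutcomeRecord("p2", "p2_o2", "neutral"),
        OutcomeRecord("p3", "p3_o1", "nonsignificant_improvement"),
    ],
    quality=[
        QualityResponse("p1", "random_allocation", "yes"),
        QualityResponse("p1", "blinded_outcome_assessment", "yes"),
        QualityResponse("p2", "random_allocation", "yes"),
        QualityResponse("p3", "random_allocation", "no"),
    ],
)

print("Per-publication domain scores (1-4; quality banded over the corpus):")
print(score_corpus(corpus).to_string())
print()
print("Ranked drugs (drug_score = S x E x Q x SS means x log10(1+n)):")
print(rank_corpus(corpus, drugs=corpus.drugs()).round(3).to_string(index=False))
print()
print("A higher drug score means more and more favourable clinical evidence;")
print("rank 1 is the strongest repurposing candidate in this corpus.")
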