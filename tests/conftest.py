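import pytest

from mndprio.records import (
    Corpus,
    OutcomeRecord,
    PreclinicalStudyRecord,
    PublicationRecord,
    QualityResponse,
)


@pytest.fixture
def small_corpus() -> Corpus:
    """Four publications over two drugs, with outcomes, checklist responses
    and preclinical studies; valid by construction."""
    pubs = [
        PublicationRecord("p1", "Memantine", "MND", 2010, "rct", 63, "ae_only", "p1_o1"),
        PublicationRecord("p2", "Memantine", "AD", 2008, "rct", 250, "none_reported", None),
        PublicationRecord("p3", "Riluzole", "MND", 1996, "rct", 959, "sae_only", "p3_o1"),
        PublicationRecord("p4", "Riluzole", "MND", 2001, "case_series", 8, "not_described", None),
    ]
    outcomes = [
        OutcomeRecord("p1", "p1_o1", "neutral"),
        OutcomeRecord("p1", "p1_o2", "significant_improvement"),
        OutcomeRecord("p2", "p2_o1", "neutral"),
        OutcomeRecord("p2", "p2_o2", "significant_improvement"),
        OutcomeRecord("p3", "p3_o1", "nonsignificant_improvement"),
        OutcomeRecord("p4", "p4_o1", "not_presented"),
    ]
    quality = [
        QualityResponse("p1", "random_allocation", "yes"),
        QualityResponse("p1", "baseline_similarity", "not_clear"),
        QualityResponse("p1", "adequate_followup", "probably_yes"),
        QualityResponse("p2", "random_allocation", "yes"),
        QualityResponse("p2", "allocation_concealment", "yes"),
        QualityResponse("p2", "intention_to_treat", "yes"),
        QualityResponse("p3", "random_allocation", "no"),
        QualityResponse("p4", "peer_reviewed_publication", "yes"),
    ]
    preclinical = [
        PreclinicalStudyRecord("s1", "Memantine", "mouse SOD1-G93A", 21, 130, 122),
        PreclinicalStudyRecord("s2", "Riluzole", "mouse SOD1-G93A", 20, 140, 140),
    ]
    return Corpus.from_records(pubs, outcomes, quality, preclinical)
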