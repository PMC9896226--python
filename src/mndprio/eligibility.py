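"""Longlisting: selecting drugs by the disease coverage of their publications.

A drug is longlisted when it is described in at least one MND publication,
or in publications in at least two of the other four diseases (AD, PD, HD,
MS).  The rule depends only on which diseases have any publication, not on
how many.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import DISEASES, Corpus

__all__ = ["DiseaseProfile", "disease_profile", "is_longlisted", "longlist", "longlist_table"]


@dataclass(frozen=True)
class DiseaseProfile:
    """Per-disease publication counts for one drug."""

    drug: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {d: int(self.counts.get(d, 0)) for d in DISEASES}
        )
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("publication counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def disease_profile(corpus: Corpus, drug: str) -> DiseaseProfile:
    """Count the drug's publications per disease (all zero if absent)."""
    pubs = corpus.publications
    counts = (
        pubs.loc[pubs["drug"] == drug, "disease"].value_counts().to_dict()
        if len(pubs)
        else {}
    )
    return DiseaseProfile(drug=drug, counts=counts)


def is_longlisted(profile: DiseaseProfile) -> bool:
    """≥1 MND publication, or publications in ≥2 distinct other diseases."""
    if profile.counts["MND"] >= 1:
        return True
    other = sum(1 for d in DISEASES if d != "MND" and profile.counts[d] >= 1)
    return other >= 2


def longlist(corpus: Corpus) -> list[str]:
    """All drugs meeting the disease-coverage rule, alphabetically."""
    return [d for d in corpus.drugs() if is_longlisted(disease_profile(corpus, d))]


def longlist_table(corpus: Corpus) -> pd.DataFrame:
    """Per-drug disease counts with the eligibility flag, one row per drug."""
    rows = []
    for drug in corpus.drugs():
        profile = disease_profile(corpus, drug)
        rows.append(
            {"drug": drug, **profile.counts, "eligible": is_longlisted(profile)}
        )
    return pd.DataFrame(rows, columns=["drug", *DISEASES, "eligible"])
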