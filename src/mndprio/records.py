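"""Core data model for the evidence corpus.

The pipeline operates on four tables: clinical publications, their reported
outcomes, their quality-checklist responses, and preclinical animal survival
studies.  Records are plain dataclasses; a :class:`Corpus` holds the four
collections as pandas DataFrames with fixed column schemas so that every
downstream stage (longlisting, scoring, ranking, preclinical synthesis) can
rely on one validated representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

#: The five neurodegenerative diseases covered by the clinical review:
#: motor neuron disease plus the four diseases considered to share
#: pivotal pathways (Alzheimer's, Parkinson's, Huntington's, MS).
DISEASES: tuple[str, ...] = ("MND", "AD", "PD", "HD", "MS")

#: Eligible clinical study designs, from single case reports up to RCTs.
DESIGNS: tuple[str, ...] = (
    "case_report",
    "case_series",
    "non_randomised",
    "crossover",
    "rct",
)

#: Per-publication worst-event safety class, ordered from least to most
#: favourable.  SUSAR = suspected unexpected serious adverse reaction,
#: SAE = serious adverse event, AE = adverse event.
SAFETY_CATEGORIES: tuple[str, ...] = (
    "not_described",
    "susar_or_mortality",
    "sae_only",
    "ae_only",
    "none_reported",
)

#: Per-outcome efficacy class, ordered from least to most favourable.
EFFICACY_CATEGORIES: tuple[str, ...] = (
    "not_presented",
    "significant_worsening",
    "neutral",
    "nonsignificant_improvement",
    "significant_improvement",
)

PUBLICATION_COLUMNS = (
    "pub_id",
    "drug",
    "disease",
    "year",
    "design",
    "n_participants",
    "safety_category",
    "primary_outcome_id",
)
OUTCOME_COLUMNS = ("pub_id", "outcome_id", "efficacy_category")
QUALITY_COLUMNS = ("pub_id", "item_id", "response")
PRECLINICAL_COLUMNS = (
    "study_id",
    "drug",
    "species_model",
    "n_animals",
    "median_survival_treated",
    "median_survival_control",
)


@dataclass(frozen=True)
class PublicationRecord:
    """One clinical publication of a drug in one of the five diseases."""

    pub_id: str
    drug: str
    disease: str
    year: int
    design: str
    n_participants: int
    safety_category: str
    primary_outcome_id: str | None = None


@dataclass(frozen=True)
class OutcomeRecord:
    """One reported outcome of a publication with its efficacy class."""

    pub_id: str
    outcome_id: str
    efficacy_category: str


@dataclass(frozen=True)
class QualityResponse:
    """One response to a quality-checklist item for a publication."""

    pub_id: str
    item_id: str
    response: str


@dataclass(frozen=True)
class PreclinicalStudyRecord:
    """One animal survival study of a drug (medians in days)."""

    study_id: str
    drug: str
    species_model: str
    n_animals: int
    median_survival_treated: float
    median_survival_control: float


def _frame(records: Iterable, columns: Sequence[str]) -> pd.DataFrame:
    rows = [vars(r) if not isinstance(r, dict) else r for r in records]
    df = pd.DataFrame(rows, columns=list(columns))
    return df


@dataclass
class Corpus:
    """The four evidence tables used by every pipeline stage.

    ``publications`` carries one row per clinical publication;
    ``outcomes`` one row per reported outcome; ``quality`` one row per
    checklist response; ``preclinical`` one row per animal survival study.
    ``primary_outcome_id`` is NA when the publication identifies no primary
    outcome (efficacy is then averaged over all its outcomes).
    """

    publications: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(PUBLICATION_COLUMNS))
    )
    outcomes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(OUTCOME_COLUMNS))
    )
    quality: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(QUALITY_COLUMNS))
    )
    preclinical: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(PRECLINICAL_COLUMNS))
    )

    @classmethod
    def from_records(
        cls,
        publications: Iterable[PublicationRecord] = (),
        outcomes: Iterable[OutcomeRecord] = (),
        quality: Iterable[QualityResponse] = (),
        preclinical: Iterable[PreclinicalStudyRecord] = (),
    ) -> "Corpus":
        return cls(
            publications=_frame(publications, PUBLICATION_COLUMNS),
            outcomes=_frame(outcomes, OUTCOME_COLUMNS),
            quality=_frame(quality, QUALITY_COLUMNS),
            preclinical=_frame(preclinical, PRECLINICAL_COLUMNS),
        )

    def drugs(self) -> list[str]:
        """Sorted canonical names of all drugs with ≥1 clinical publication."""
        return sorted(self.publications["drug"].dropna().unique())

    def equals(self, other: "Corpus") -> bool:
        """Field-by-field equality of all four tables (row order sensitive)."""

        def _eq(a: pd.DataFrame, b: pd.DataFrame) -> bool:
            a = a.reset_index(drop=True)
            b = b.reset_index(drop=True)
            if list(a.columns) != list(b.columns) or len(a) != len(b):
                return False
            return bool(a.fillna("").astype(str).eq(b.fillna("").astype(str)).all().all())

        return (
            _eq(self.publications, other.publications)
            and _eq(self.outcomes, other.outcomes)
            and _eq(self.quality, other.quality)
            and _eq(self.preclinical, other.preclinical)
        )
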