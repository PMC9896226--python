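"""Per-drug aggregation: domain means, the drug score, and ranking.

For each drug the four per-publication domain scores are averaged, and the
ranking statistic is

    drug_score = S̄ × Ē × Q̄ × SS̄ × log10(1 + n_publications)

where S̄, Ē, Q̄, SS̄ are the mean safety, efficacy, quality-band and
study-size scores over the drug's publications and n_publications is its
publication count.  Scores are carried at full precision and rounded
(half-up, 2 decimals) only for reporting; ranks are assigned in descending
score order with alphabetical tie-breaks.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .eligibility import longlist
from .records import DISEASES, Corpus
from .scoring import score_corpus

__all__ = [
    "round_half_up",
    "domain_means",
    "drug_score",
    "rank_drugs",
    "rank_corpus",
    "disease_summary",
]

#: Column order of the ranking report.
RANKING_COLUMNS = (
    "intervention",
    "n_publications",
    "quality",
    "efficacy",
    "safety",
    "study_size",
    "drug_score",
    "rank",
)


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal round-half-up (0.905 → 0.91 at 2 digits), for report values."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def domain_means(scores: pd.DataFrame) -> tuple[dict[str, float], int]:
    """Mean safety/efficacy/quality/study-size over one drug's publications.

    ``scores`` holds the per-publication domain scores (one row each).
    Returns the four means and the publication count.
    """
    if len(scores) == 0:
        raise ValueError("domain means require at least one publication")
    means = {
        "safety": float(scores["safety"].mean()),
        "efficacy": float(scores["efficacy"].mean()),
        "quality": float(scores["quality"].mean()),
        "study_size": float(scores["study_size"].mean()),
    }
    return means, len(scores)


def drug_score(means: Mapping[str, float] | Sequence[float], n_publications: int) -> float:
    """The ranking statistic: product of the four domain means × log10(1+n).

    ``means`` is either the mapping returned by :func:`domain_means` or a
    sequence of four numbers.  The result is returned unrounded; use
    :func:`round_half_up` for the 2-decimal report value.
    """
    if n_publications < 1:
        raise ValueError("publication count must be ≥ 1")
    if isinstance(means, Mapping):
        values = [means["safety"], means["efficacy"], means["quality"], means["study_size"]]
    else:
        values = list(means)
    if len(values) != 4:
        raise ValueError("expected four domain means")
    product = 1.0
    for v in values:
        product *= float(v)
    return product * math.log10(1 + n_publications)


def rank_drugs(scorecards: pd.DataFrame) -> pd.DataFrame:
    """Order scorecards by descending unrounded drug score.

    Ties are broken alphabetically by intervention name; ranks are 1..K
    without gaps.
    """
    if scorecards.empty:
        raise ValueError("nothing to rank")
    out = scorecards.sort_values(
        by=["drug_score", "intervention"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def rank_corpus(
    corpus: Corpus,
    drugs: Sequence[str] | None = None,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score and rank drugs of a corpus (the longlist by default).

    Quality banding is computed over the *whole* corpus before
    aggregation.  Returns one row per drug with the report columns
    (intervention, n_publications, the four domain means, drug_score,
    rank); means and scores are unrounded.
    """
    if scores is None:
        scores = score_corpus(corpus)
    if drugs is None:
        drugs = longlist(corpus)
    pubs = corpus.publications
    rows = []
    for drug in drugs:
        pub_ids = pubs.loc[pubs["drug"] == drug, "pub_id"]
        drug_scores = scores.loc[scores.index.isin(pub_ids)]
        if len(drug_scores) == 0:
            continue
        means, n = domain_means(drug_scores)
        rows.append(
            {
                "intervention": drug,
                "n_publications": n,
                "quality": means["quality"],
                "efficacy": means["efficacy"],
                "safety": means["safety"],
                "study_size": means["study_size"],
                "drug_score": drug_score(means, n),
            }
        )
    if not rows:
        return pd.DataFrame(columns=list(RANKING_COLUMNS))
    return rank_drugs(pd.DataFrame(rows))[list(RANKING_COLUMNS)]


def disease_summary(corpus: Corpus, drugs: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-drug, per-disease publication and participant counts with totals.

    Columns: ``drug``, ``pubs_<disease>`` and ``participants_<disease>``
    for each of the five diseases, plus ``pubs_total`` and
    ``participants_total`` (row sums of the per-disease cells).
    """
    if drugs is None:
        drugs = corpus.drugs()
    pubs = corpus.publications
    rows = []
    for drug in drugs:
        sub = pubs.loc[pubs["drug"] == drug]
        row: dict[str, object] = {"drug": drug}
        for d in DISEASES:
            in_d = sub.loc[sub["disease"] == d]
            row[f"pubs_{d}"] = len(in_d)
            row[f"participants_{d}"] = int(in_d["n_participants"].sum())
        row["pubs_total"] = sum(row[f"pubs_{d}"] for d in DISEASES)
        row["participants_total"] = sum(row[f"participants_{d}"] for d in DISEASES)
        rows.append(row)
    columns = (
        ["drug"]
        + [f"pubs_{d}" for d in DISEASES]
        + ["pubs_total"]
        + [f"participants_{d}" for d in DISEASES]
        + ["participants_total"]
    )
    return pd.DataFrame(rows, columns=columns)
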