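"""Per-publication domain scores: safety, efficacy, quality and study size.

Each clinical publication receives four scores on a 1–4 scale:

* **Safety** from the worst-event class reported (not described or
  SUSARs/mortality = 1, SAEs only = 2, AEs only = 3, none reported = 4).
* **Efficacy** from the primary outcome's class when one is identified,
  otherwise the mean over all reported outcomes (not presented /
  significant worsening = 1, neutral = 2, non-significant improvement = 3,
  significant improvement = 4).  Efficacy means are carried unrounded.
* **Quality** by corpus-relative quartile banding of the raw 21-item
  checklist total (0–21 points): publications in the lowest quartile score
  1, the highest 4.
* **Study size** from participant count bins (1–10, 11–100, 101–1000,
  >1000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .records import Corpus
from .registry import RESPONSE_POINTS, checklist_items, is_legal_response

__all__ = [
    "DomainScores",
    "safety_score",
    "efficacy_points",
    "efficacy_score",
    "quality_raw",
    "quality_band",
    "study_size_score",
    "score_corpus",
]

SAFETY_POINTS: dict[str, int] = {
    "not_described": 1,
    "susar_or_mortality": 1,
    "sae_only": 2,
    "ae_only": 3,
    "none_reported": 4,
}

EFFICACY_POINTS: dict[str, int] = {
    "not_presented": 1,
    "significant_worsening": 1,
    "neutral": 2,
    "nonsignificant_improvement": 3,
    "significant_improvement": 4,
}


@dataclass(frozen=True)
class DomainScores:
    """The four domain scores of one publication (quality corpus-banded)."""

    pub_id: str
    safety: float
    efficacy: float
    quality_raw: float
    quality: int
    study_size: int


def safety_score(category: str) -> int:
    """Safety points (1–4) for a worst-event safety class."""
    try:
        return SAFETY_POINTS[category]
    except KeyError:
        raise ValueError(f"unknown safety category {category!r}") from None


def efficacy_points(category: str) -> int:
    """Efficacy points (1–4) for one outcome's efficacy class."""
    try:
        return EFFICACY_POINTS[category]
    except KeyError:
        raise ValueError(f"unknown efficacy category {category!r}") from None


def efficacy_score(
    primary_outcome_id: str | None,
    outcomes: Mapping[str, str] | pd.DataFrame,
) -> float:
    """Publication-level efficacy score.

    ``outcomes`` maps outcome_id → efficacy category (or is a DataFrame
    with those columns).  With an identified primary outcome the score is
    that outcome's points; otherwise the mean over all outcomes.  A
    publication with no recorded outcomes scores 1 ("not presented"), with
    a warning.
    """
    if isinstance(outcomes, pd.DataFrame):
        outcomes = dict(zip(outcomes["outcome_id"], outcomes["efficacy_category"]))
    if primary_outcome_id is not None and not pd.isna(primary_outcome_id):
        if primary_outcome_id not in outcomes:
            raise ValueError(f"primary outcome {primary_outcome_id!r} not among outcomes")
        return float(efficacy_points(outcomes[primary_outcome_id]))
    if not outcomes:
        warnings.warn("publication has no recorded outcomes; efficacy scored 1", stacklevel=2)
        return 1.0
    return float(np.mean([efficacy_points(c) for c in outcomes.values()]))


def quality_raw(responses: Mapping[str, str]) -> float:
    """Raw checklist total (0–21) for one publication.

    ``responses`` maps item_id → response.  Missing items and ``na``
    contribute 0; the total is not rescaled (banding is corpus-relative).
    """
    registry = checklist_items()
    total = 0.0
    for item_id, response in responses.items():
        if item_id not in registry:
            raise ValueError(f"unknown checklist item {item_id!r}")
        if not is_legal_response(item_id, response):
            raise ValueError(
                f"response {response!r} illegal for "
                f"{registry[item_id].response_class} item {item_id!r}"
            )
        total += RESPONSE_POINTS[response]
    return total


def quality_band(raw_scores: Mapping[str, float]) -> dict[str, int]:
    """Quartile-band raw quality totals over the whole scored corpus.

    Thresholds are the empirical 25th/50th/75th percentiles
    (linear-interpolation quantiles) of the raw scores; a publication's
    band is 1 plus the number of thresholds its raw score strictly
    exceeds, so ties at a threshold fall to the lower band and the result
    is order-invariant.
    """
    if not raw_scores:
        raise ValueError("quality banding requires at least one publication")
    values = np.asarray(list(raw_scores.values()), dtype=float)
    thresholds = np.percentile(values, [25, 50, 75])
    return {
        pub_id: 1 + int(np.sum(raw > thresholds))
        for pub_id, raw in raw_scores.items()
    }


def study_size_score(n_participants: int) -> int:
    """Study-size points: 1–10 → 1; 11–100 → 2; 101–1000 → 3; >1000 → 4."""
    n = int(n_participants)
    if n < 1:
        raise ValueError("participant count must be ≥ 1")
    if n <= 10:
        return 1
    if n <= 100:
        return 2
    if n <= 1000:
        return 3
    return 4


def score_corpus(corpus: Corpus) -> pd.DataFrame:
    """All four domain scores for every publication in the corpus.

    Quality banding is computed over the full corpus in the same call.
    Returns a DataFrame indexed by pub_id with columns ``safety``,
    ``efficacy``, ``quality_raw``, ``quality``, ``study_size``; row order
    follows the publications table but scores are order-invariant.
    """
    pubs = corpus.publications
    if pubs.empty:
        return pd.DataFrame(
            columns=["safety", "efficacy", "quality_raw", "quality", "study_size"]
        )
    outcome_groups = {
        pid: grp for pid, grp in corpus.outcomes.groupby("pub_id", sort=False)
    }
    quality_groups = {
        pid: dict(zip(grp["item_id"], grp["response"]))
        for pid, grp in corpus.quality.groupby("pub_id", sort=False)
    }

    raw: dict[str, float] = {}
    rows: dict[str, dict] = {}
    for _, pub in pubs.iterrows():
        pid = pub["pub_id"]
        outs = outcome_groups.get(pid)
        outs_map = (
            dict(zip(outs["outcome_id"], outs["efficacy_category"])) if outs is not None else {}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eff = efficacy_score(pub["primary_outcome_id"], outs_map)
        raw[pid] = quality_raw(quality_groups.get(pid, {}))
        rows[pid] = {
            "safety": float(safety_score(pub["safety_category"])),
            "efficacy": eff,
            "quality_raw": raw[pid],
            "study_size": study_size_score(pub["n_participants"]),
        }
    bands = quality_band(raw)
    for pid, row in rows.items():
        row["quality"] = bands[pid]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "pub_id"
    return df[["safety", "efficacy", "quality_raw", "quality", "study_size"]]
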