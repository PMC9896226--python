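"""Preclinical survival synthesis: the log median-survival ratio (LogMSR).

For an animal survival study the effect statistic is

    LogMSR = ln(median survival, treated / median survival, control)

which is positive when treatment prolongs survival, zero when medians are
equal, and unit-free (scale-invariant in the medians).  Per-drug summaries
count studies by the sign of LogMSR; a drug's preclinical evidence is
"supportive" when at least one study shows a survival benefit (a
configurable minimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .prioritize import round_half_up
from .records import Corpus

__all__ = ["PreclinicalSummary", "logmsr", "study_table", "summarize_preclinical"]


def logmsr(median_treated: float, median_control: float) -> float:
    """Natural log of the treated/control median-survival ratio.

    Returned unrounded; reports round to 4 decimals.  Antisymmetric in its
    arguments and invariant to rescaling both medians.
    """
    if median_treated <= 0 or median_control <= 0:
        raise ValueError("median survivals must be strictly positive")
    return math.log(median_treated / median_control)


@dataclass(frozen=True)
class PreclinicalSummary:
    """Aggregate of all survival studies of one drug."""

    drug: str
    n_studies: int
    n_animals_total: int
    logmsr_values: tuple[float, ...] = field(default_factory=tuple)
    median_logmsr: float = float("nan")
    n_positive: int = 0
    n_zero: int = 0
    n_negative: int = 0
    supportive: bool = False


def study_table(corpus: Corpus, digits: int = 4) -> pd.DataFrame:
    """Study-level LogMSR for every preclinical record, rounded for report."""
    df = corpus.preclinical.copy()
    if df.empty:
        df["logmsr"] = pd.Series(dtype=float)
        return df
    df["logmsr"] = [
        round_half_up(logmsr(t, c), digits)
        for t, c in zip(df["median_survival_treated"], df["median_survival_control"])
    ]
    return df


def summarize_preclinical(
    corpus: Corpus, drug: str, min_positive: int = 1
) -> PreclinicalSummary:
    """Summarise all survival studies of one drug.

    ``supportive`` is true when at least ``min_positive`` studies have
    LogMSR > 0.  A drug with no studies yields an empty, non-supportive
    summary.
    """
    sub = corpus.preclinical.loc[corpus.preclinical["drug"] == drug]
    if sub.empty:
        return PreclinicalSummary(drug=drug, n_studies=0, n_animals_total=0)
    values = tuple(
        logmsr(t, c)
        for t, c in zip(sub["median_survival_treated"], sub["median_survival_control"])
    )
    series = pd.Series(values)
    n_pos = int((series > 0).sum())
    return PreclinicalSummary(
        drug=drug,
        n_studies=len(sub),
        n_animals_total=int(sub["n_animals"].sum()),
        logmsr_values=values,
        median_logmsr=float(series.median()),
        n_positive=n_pos,
        n_zero=int((series == 0).sum()),
        n_negative=int((series < 0).sum()),
        supportive=n_pos >= min_positive,
    )


def summary_table(corpus: Corpus, min_positive: int = 1) -> pd.DataFrame:
    """Per-drug preclinical summaries for every drug with survival data."""
    rows = []
    for drug in sorted(corpus.preclinical["drug"].unique()):
        s = summarize_preclinical(corpus, drug, min_positive=min_positive)
        rows.append(
            {
                "drug": s.drug,
                "n_studies": s.n_studies,
                "n_animals_total": s.n_animals_total,
                "median_logmsr": round_half_up(s.median_logmsr, 4),
                "n_positive": s.n_positive,
                "n_zero": s.n_zero,
                "n_negative": s.n_negative,
                "supportive": s.supportive,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "n_studies",
            "n_animals_total",
            "median_logmsr",
            "n_positive",
            "n_zero",
            "n_negative",
            "supportive",
        ],
    )
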