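"""Rule engine for expert-panel shortlisting.

Over the shortlisting rounds the panel rates each drug green (most
favourable), amber or red (least favourable) on five criteria: biological
plausibility, safety profile, clinical evidence, preclinical evidence and
logistics.  A drug is excluded when any criterion is rated red, or when it
has been tested in more than three previous MND clinical trials.  Panel
judgements that follow no stated rule (round-2 "aggregate judgement"
exclusions) are carried as explicit per-drug overrides, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CRITERIA",
    "RATINGS",
    "ShortlistInput",
    "ShortlistDecision",
    "apply_exclusion_rules",
    "run_round",
    "read_shortlist_inputs",
]

#: The five rated criteria, and the exclusion reason each red rating emits.
CRITERIA: tuple[str, ...] = (
    "biological_plausibility",
    "safety_profile",
    "clinical_evidence",
    "preclinical_evidence",
    "logistics",
)

RATINGS: tuple[str, ...] = ("green", "amber", "red")

TRIAL_CAP = 3
TRIAL_CAP_REASON = ">3 previous clinical trials in MND"

RED_REASONS: dict[str, str] = {
    "biological_plausibility": "Poor biological plausibility",
    "safety_profile": "Unfavourable safety profile",
    "clinical_evidence": "Unfavourable clinical evidence",
    "preclinical_evidence": "Unfavourable preclinical evidence",
    "logistics": "Unfavourable logistics",
}


@dataclass(frozen=True)
class ShortlistInput:
    """One drug's panel ratings, prior-trial count and optional override."""

    drug: str
    ratings: Mapping[str, str]
    n_prior_mnd_trials: int = 0
    override_exclude: str | None = None  # free-text reason for a non-rule exclusion

    def __post_init__(self) -> None:
        missing = [c for c in CRITERIA if c not in self.ratings]
        if missing:
            raise ValueError(f"{self.drug}: missing criteria {missing}")
        bad = {c: r for c, r in self.ratings.items() if c in CRITERIA and r not in RATINGS}
        if bad:
            raise ValueError(f"{self.drug}: illegal ratings {bad}")
        if self.n_prior_mnd_trials < 0:
            raise ValueError(f"{self.drug}: negative prior-trial count")


@dataclass(frozen=True)
class ShortlistDecision:
    """The outcome for one drug: retained iff no exclusion reason fired."""

    drug: str
    retained: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)
    round: int = 1


def apply_exclusion_rules(inp: ShortlistInput, round_id: int = 1) -> ShortlistDecision:
    """Apply the exclusion rules to one drug.

    Excluded iff any criterion is red, the drug exceeds three prior MND
    trials, or an explicit override is set.  Reasons list every triggered
    rule: trial cap first, then red criteria alphabetically, then the
    override.
    """
    reasons: list[str] = []
    if inp.n_prior_mnd_trials > TRIAL_CAP:
        reasons.append(TRIAL_CAP_REASON)
    for criterion in sorted(CRITERIA):
        if inp.ratings[criterion] == "red":
            reasons.append(RED_REASONS[criterion])
    if inp.override_exclude:
        reasons.append(inp.override_exclude)
    return ShortlistDecision(
        drug=inp.drug, retained=not reasons, reasons=tuple(reasons), round=round_id
    )


def run_round(
    inputs: Iterable[ShortlistInput], round_id: int = 1
) -> tuple[list[ShortlistDecision], list[str]]:
    """Apply the rules to every drug in a round.

    Decisions depend only on each drug's own record.  Returns the audit
    list of decisions (input order) and the retained drugs (alphabetical).
    """
    decisions = [apply_exclusion_rules(inp, round_id) for inp in inputs]
    retained = sorted(d.drug for d in decisions if d.retained)
    return decisions, retained


def decisions_table(decisions: Iterable[ShortlistDecision]) -> pd.DataFrame:
    """Audit table of decisions: drug, round, retained, reasons ('; '-joined)."""
    return pd.DataFrame(
        [
            {
                "drug": d.drug,
                "round": d.round,
                "retained": d.retained,
                "reasons": "; ".join(d.reasons),
            }
            for d in decisions
        ],
        columns=["drug", "round", "retained", "reasons"],
    )


def read_shortlist_inputs(path: str | Path) -> list[ShortlistInput]:
    """Read shortlist inputs from CSV.

    Columns: drug, the five criteria, n_prior_mnd_trials, and optional
    override_exclude (empty = no override).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"drug", *CRITERIA, "n_prior_mnd_trials"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    inputs = []
    for _, row in df.iterrows():
        inputs.append(
            ShortlistInput(
                drug=row["drug"],
                ratings={c: row[c] for c in CRITERIA},
                n_prior_mnd_trials=int(row["n_prior_mnd_trials"]),
                override_exclude=row.get("override_exclude", "") or None,
            )
        )
    return inputs
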