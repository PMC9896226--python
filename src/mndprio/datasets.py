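"""Packaged reference datasets from the published repurposing review.

Small CSVs shipped with the package, used as reproduction fixtures and by
the examples:

* :func:`load_clinical_ranking` — the 66 longlisted interventions with
  their publication counts, printed domain means and drug scores.
* :func:`load_preclinical_survival` — the 36 mouse survival studies with
  treated/control median survival and the printed LogMSR.
* :func:`load_disease_summary` — per-disease publication and participant
  counts for the seven final shortlisted drugs.
* :func:`load_panel_exclusions` — the drugs excluded by the expert panel
  with round and stated reason.
* :func:`round1_shortlist_inputs` — panel ratings for the 22 shortlisted
  drugs reconstructed from the stated exclusion reasons, suitable for
  :func:`mndprio.shortlist.run_round`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .shortlist import CRITERIA, RED_REASONS, TRIAL_CAP_REASON, ShortlistInput

__all__ = [
    "load_clinical_ranking",
    "load_preclinical_survival",
    "load_disease_summary",
    "load_panel_exclusions",
    "round1_shortlist_inputs",
]

#: Drugs that survived both shortlisting rounds.
FINAL_SHORTLIST = (
    "Memantine",
    "Acetyl-L-carnitine",
    "Simvastatin",
    "Ciclosporin",
    "Melatonin",
    "Fluoxetine",
    "N-acetyl cysteine",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("mndprio.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_clinical_ranking() -> pd.DataFrame:
    """The ranked longlist: intervention, n_publications, the four domain
    means (quality, efficacy, safety, study_size) and the drug score."""
    return _read("clinical_ranking.csv")


def load_preclinical_survival() -> pd.DataFrame:
    """Mouse survival studies: publication, drug, animal count,
    treated/control median survival (days) and printed LogMSR."""
    return _read("preclinical_survival.csv")


def load_disease_summary() -> pd.DataFrame:
    """Per-disease publication/participant counts for the final shortlist."""
    return _read("disease_summary.csv")


def load_panel_exclusions() -> pd.DataFrame:
    """Expert-panel exclusions: drug, shortlisting round, stated reason."""
    return _read("panel_exclusions.csv")


_REASON_TO_CRITERION = {reason: criterion for criterion, reason in RED_REASONS.items()}


def round1_shortlist_inputs() -> list[ShortlistInput]:
    """Round-1 panel inputs for the 22 shortlisted drugs.

    Ratings are reconstructed from the stated exclusion reasons: a drug
    excluded for an unfavourable criterion is rated red there; a drug
    excluded for exceeding three prior MND trials carries a trial count of
    4; every other rating is green and every other trial count 0.  Drugs
    not excluded in round 1 (including the round-2 exclusions) are all
    green with ≤3 prior trials.
    """
    exclusions = load_panel_exclusions()
    round1 = exclusions.loc[exclusions["round"] == 1]
    round2 = exclusions.loc[exclusions["round"] == 2]
    inputs: list[ShortlistInput] = []
    for _, row in round1.iterrows():
        ratings = {c: "green" for c in CRITERIA}
        trials = 0
        if row["reason"] == TRIAL_CAP_REASON:
            trials = 4
        else:
            ratings[_REASON_TO_CRITERION[row["reason"]]] = "red"
        inputs.append(
            ShortlistInput(drug=row["drug"], ratings=ratings, n_prior_mnd_trials=trials)
        )
    for drug in list(round2["drug"]) + list(FINAL_SHORTLIST):
        inputs.append(
            ShortlistInput(
                drug=drug,
                ratings={c: "green" for c in CRITERIA},
                n_prior_mnd_trials=0,
            )
        )
    assert len(inputs) == 22
    return inputs
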