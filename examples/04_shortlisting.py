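"""Expert-panel shortlisting: red ratings and the prior-trial cap.

Drugs rated red on any of the five criteria (biological plausibility,
safety profile, clinical evidence, preclinical evidence, logistics) are
excluded, as are drugs with more than three previous MND trials.  The
round-1 inputs here are reconstructed from the published exclusion
reasons.
"""

from mndprio.datasets import round1_shortlist_inputs
from mndprio.shortlist import decisions_table, run_round

decisions, retained = run_round(round1_shortlist_inputs(), round_id=1)
table = decisions_table(decisions)

print("Round-1 decisions:")
print(table.to_string(index=False))
print()
print(f"Retained {len(retained)} of {len(decisions)} drugs: {', '.join(retained)}")
print()
print("Every exclusion lists the rule that fired; a drug with exactly three")
print("prior MND trials would still be retained (the cap is 'more than three').")
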