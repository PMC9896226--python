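"""Validate the ranking on synthetic corpora with known ground truth.

Generates corpora in which each drug has a latent log-scale benefit that
shifts its efficacy outcomes and preclinical survival ratios, runs the
full score-and-rank pipeline, and measures the Spearman correlation
between latent benefit and drug score.  A slope-0 null shows what the
correlation looks like when the evidence carries no signal.
"""

from mndprio import SimulationConfig, ranking_recovery

strong = ranking_recovery(SimulationConfig(seed=2024, n_drugs=50), n_reps=10)
null = ranking_recovery(
    SimulationConfig(seed=2024, n_drugs=50, efficacy_slope=0.0, preclinical_slope=0.0),
    n_reps=10,
)

print(f"Monotone efficacy link: mean Spearman rho = {strong.mean:.3f} (SE {strong.se:.3f})")
print(f"Null (slope 0):         mean Spearman rho = {null.mean:.3f} (SE {null.se:.3f})")
print()
print("Under the monotone link, drugs simulated with larger latent benefit")
print("earn systematically higher drug scores; under the null the")
print("correlation is indistinguishable from zero.")
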