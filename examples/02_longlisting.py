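"""The longlisting rule: disease coverage decides eligibility.

A drug enters the longlist if it has at least one MND publication, or
publications in at least two of the other four diseases (AD, PD, HD, MS).
Only the support pattern matters, not how many publications each disease
has.
"""

from mndprio import DiseaseProfile, is_longlisted

profiles = [
    DiseaseProfile("Memantine", {"MND": 1, "AD": 32, "HD": 2, "MS": 1, "PD": 15}),
    DiseaseProfile("Acetyl-L-carnitine", {"AD": 9, "HD": 1}),
    DiseaseProfile("Single-disease drug", {"AD": 5}),
]

for profile in profiles:
    verdict = "longlisted" if is_longlisted(profile) else "not longlisted"
    counts = {d: c for d, c in profile.counts.items() if c}
    print(f"{profile.drug:25s} {counts} -> {verdict}")

print()
print("Memantine qualifies through its MND publication; acetyl-L-carnitine")
print("through coverage of two non-MND diseases; five AD papers alone are")
print("not enough, however many there are.")
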