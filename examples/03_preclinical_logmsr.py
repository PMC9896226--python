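"""LogMSR: the preclinical survival effect statistic.

For each mouse survival study, LogMSR = ln(median survival treated /
median survival control): positive when treatment extends survival.
Recomputes the statistic for the packaged reference studies and
summarises one drug.
"""

from mndprio import logmsr, round_half_up, summarize_preclinical
from mndprio.datasets import load_preclinical_survival
from mndprio.records import Corpus, PreclinicalStudyRecord

ref = load_preclinical_survival()
print("First five survival studies, LogMSR recomputed from the medians:")
for row in ref.head(5).itertuples():
    value = round_half_up(
        logmsr(row.median_survival_treated, row.median_survival_control), 4
    )
    print(
        f"  {row.publication:20s} {row.drug:20s} "
        f"{row.median_survival_treated:>5g}/{row.median_survival_control:<5g} "
        f"LogMSR={value:+.4f} (printed {row.logmsr:+.4f})"
    )

lithium = Corpus.from_records(
    preclinical=[
        PreclinicalStudyRecord(f"s{i}", "Lithium", "mouse SOD1-G93A", 20, t, c)
        for i, (t, c) in enumerate([(146, 117), (124, 127), (119, 129)])
    ]
)
summary = summarize_preclinical(lithium, "Lithium")
print()
print(
    f"Lithium: {summary.n_studies} studies, "
    f"{summary.n_positive} positive / {summary.n_negative} negative, "
    f"median LogMSR {summary.median_logmsr:+.4f}, supportive={summary.supportive}"
)
print()
print("One positive study is enough to count the preclinical evidence as")
print("supportive under the default (weakest defensible) threshold.")
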