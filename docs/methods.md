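# Methods

## The prioritisation model

The package ranks repurposing candidates for motor neuron disease from a
corpus of pre-annotated evidence records. It assumes the evidence has
already been screened into structured tables: clinical publications
(drug, disease, design, participant count, a single worst-event safety
class, per-outcome efficacy classes, checklist responses) and preclinical
animal survival studies (treated/control median survival). No text mining
or bibliographic retrieval happens here; annotation quality is an input
assumption.

### Longlisting

A drug enters the longlist when it has at least one MND publication or
publications in at least two *distinct* other diseases (AD, PD, HD, MS).
Distinct diseases — not publication counts — carry the signal: the rule is
a function of the support pattern only, which makes it monotone under
adding publications. MS records are counted regardless of subtype because
subtype exclusions (e.g. relapsing-remitting disease) belong to
record-level screening, upstream of this package.

### Domain scores

* **Safety** maps the worst-event class to 1–4 (not described and
  SUSARs/mortality both score 1; SAEs only 2; AEs only 3; none reported 4).
  The class is a single mutually-exclusive tier fixed at data entry.
* **Efficacy** uses the primary outcome's class when the publication
  identifies one, otherwise the unweighted mean over all its outcomes
  (classes score: not presented / significant worsening 1, neutral 2,
  non-significant improvement 3, significant improvement 4). A publication
  with no recorded outcomes scores 1, with a warning. Fractional means are
  carried unrounded through aggregation.
* **Quality** sums the 21-item checklist (6 binary, 8 tertiary, 7 quinary
  items; see `mndprio/data/quality_items.json`) into a raw 0–21 total,
  then bands the total into quartiles over the *whole scored corpus*:
  thresholds are the 25th/50th/75th linear-interpolation percentiles and a
  publication's band is 1 plus the number of thresholds its total strictly
  exceeds. Ties at a threshold fall to the lower band — the rule is
  deterministic and order-invariant, which an "assign quartiles by sorted
  position" rule is not under ties. The total is interpreted as checklist
  *points* (not the count of items answered), since the banding is meant to
  order publications by quality. `na` responses and unanswered items
  contribute 0 without rescaling the denominator; any rescaling convention
  would be an invention, and banding is relative so only the ordering
  matters when missingness is comparable across publications.
  Banding pools all diseases: the exercise is one corpus-wide ranking.
* **Study size** bins participants: 1–10 → 1, 11–100 → 2, 101–1000 → 3,
  >1000 → 4.

### The drug score

`drug_score = mean(S) · mean(E) · mean(Q) · mean(SS) · log10(1 + n)` over a
drug's n publications. The log-10 weight is confirmed against the shipped
reference ranking (a drug with means 1·1·3·1 and n=1 scores
3·log10 2 = 0.90; a natural log would give 2.08). Scores are stored at
full precision; reports round half-up to 2 decimals. Ranking sorts on the
unrounded score, ties broken alphabetically — the reference table's order
is consistent with either rounded or unrounded sorting, so the
deterministic choice is free.

### Preclinical survival statistic

`LogMSR = ln(treated median / control median)`, natural log (verified:
medians 24/12 print 0.6931 = ln 2, not 0.3010). It is antisymmetric,
scale-invariant and unit-free, so unstated units in source tables do not
affect it. A drug's preclinical evidence is "supportive" when at least one
study has LogMSR > 0 — the weakest defensible reading of "supportive
evidence", configurable via `min_positive`. No random-effects pooling or
survival-curve modelling is attempted; behavioural outcomes carry no
defined statistic and are not synthesised.

### Shortlisting rules

Exclusion iff any of the five criteria is rated red or the drug has more
than three prior MND trials (exactly three is retained). Reasons are
reported in a fixed order: trial cap first, then red criteria
alphabetically. Decisions are per-drug with no cross-drug coupling.
Panel exclusions that follow no stated rule ("aggregate judgement") are
representable only as explicit `override_exclude` entries in the input
file; inferring them from data would misrepresent a judgement as a rule.

## Synthetic corpus generator

The generator emulates the statistical shape of a review corpus while
attaching a known latent benefit to each drug:

* latent effect ~ Normal(0, `effect_sd`=0.5) on a log scale;
* disease coverage: independent Bernoulli per disease
  (MND 0.35, AD 0.45, PD 0.40, HD 0.15, MS 0.30 — most drugs cover one to
  three diseases, as in review-scale corpora), with a forced single
  disease if all draws fail;
* publications per covered disease: zero-truncated negative binomial
  (mean 3, dispersion 1.5), matching a corpus of ~50–70 drugs and a few
  hundred publications;
* participants: log-normal (ln-scale mean 3.4, sd 1.6), spanning
  single-figure case reports to >1000-participant trials;
* efficacy: a proportional-odds shift of a baseline five-category
  distribution, moving mass toward improvement monotonically in the latent
  effect — the simplest monotone link that produces all categories;
* safety class, study design and checklist responses: independent
  categorical draws (design independent of effect; checklist items
  independent across items — no dependence structure is needed to test
  scoring and banding);
* preclinical: study count ~ Poisson(0.6) per drug (roughly a third of
  drugs carry survival data), control median log-normal around 130 days,
  treated median = control × exp(0.15 × effect + Normal(0, 0.05)).

What it does **not** emulate: citation text, screening disagreement,
correlated quality items, publication bias, or any dependence of study
design on effect. Passing ranking-recovery tests therefore show that the
pipeline orders drugs correctly *when the evidence behaves as modelled*,
not that real annotated corpora are unbiased.

Determinism: one `numpy` generator seeded from the config; the same config
and seed produce byte-identical CSVs. Replicate seeds in
`ranking_recovery` are drawn below 2³¹ from a master generator.

## Numerical choices

* Report rounding is decimal half-up (2 decimals for scores, 4 for
  LogMSR), matching how the reference tables print; computation is always
  on unrounded values.
* Quartile thresholds use numpy's linear-interpolation percentiles.
* Degenerate inputs: a single-publication corpus bands quality 1; equal
  raw quality scores all band 1; a drug absent from the corpus yields an
  all-zero disease profile and an empty, non-supportive preclinical
  summary; empty banding input and zero-publication domain means raise.
* Drug-name matching folds case, whitespace and hyphens; unknown names
  pass through trimmed with whitespace collapsed, so normalisation is
  idempotent and canonical names are fixed points. Combination products
  (e.g. "Dextromethorphan/quinidine") are distinct canonical drugs.

## Problem sizes

The test suite exercises banding up to 400 publications and ranking
recovery at 50 drugs × 20 replicates against a slope-0 null — sizes chosen
to put Monte-Carlo error well below the effects being detected while
keeping the default run fast.

## Known limitations

* Quality banding is corpus-relative: a publication's quality band changes
  when the corpus changes, so bands are not comparable across corpora.
* The drug score conflates evidence volume with favourability by design;
  it is a screening statistic, not an effect estimate.
* "Supportive" preclinical evidence ignores study size and precision; a
  single small positive study qualifies under the default threshold.
* The rule engine reproduces panel *rules*, not panel *judgement*; final
  candidate choice remains a human decision informed by these outputs.
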