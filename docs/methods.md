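# Methods

`opioidpgx` implements a retrospective new-user cohort analysis of whether
reduced CYP2D6 activity — genetic, drug-induced, or both — is associated
with pain-related emergency-department (ED) visits among adults prescribed
CYP2D6-metabolized opioids (hydrocodone, tramadol, codeine, oxycodone).
This note records the models, conventions, and design choices, and what the
synthetic validation does and does not establish.

## Phenotype model

Each CYP2D6 star allele carries an activity value: functional alleles
(*1, *2, *35) score 1; reduced-function alleles *9, *17, *29, *41 score 0.5
and *10 scores 0.25; non-functional alleles (*3–*8, *11, *15) score 0.
A duplication `*NxK` contributes K times the base value, following the CPIC
activity-score convention. The genotype activity score is the sum over the
two alleles of the diplotype, and maps to a metabolizer category:

| category | score |
|---|---|
| ultrarapid (UM) | > 2.25 |
| normal (NM) | 1.25 – 2.25 (inclusive on both ends) |
| intermediate (IM) | (0, 1.25) |
| poor (PM) | 0 |

The boundary scores 1.25 and 2.25 classify as NM because the category
definitions are inclusive at those points. A concomitant CYP2D6 inhibitor
rescales the score multiplicatively before classification: factor 0 for a
strong inhibitor, 0.5 for moderate, 1 for none ("phenoconversion"; the
adjusted categories are written pUM/pNM/pIM/pPM). Phenoconversion can never
raise the score, so the adjusted category is never faster than the genetic
one.

Alleles absent from the activity table make the person's phenotype
Indeterminate (and excluded downstream) rather than guessing a value. The
allele table, cut-points, and factor map are configuration, so guideline
updates need no code change; shipped defaults are the values above.

**Consensus calling.** Up to four haplotype callers report a diplotype per
person. The consensus is the canonical diplotype (allele order normalized)
reported by at least 2 tools that is also a strict majority of the tools
that produced a call; otherwise the genotype is Indeterminate. Strict
majority is computed over tools *with* a call, not all tools run, and a 2–2
split is Indeterminate — the rule names the ≥2-tool floor and the majority
separately, and both are enforced. Both choices are configuration.

## Exposure eras

Prescriptions carry only a start date and dispensed quantity; directions are
assumed to be 4 tablets/day for every drug, so days-supply =
ceil(quantity/4) and the imputed end date is start + supply − 1 (intervals
include both endpoints). Refills of the same drug merge into one exposure
episode when the gap (next start − previous end − 1 days) is:

- **< 14 days** for opioids,
- **≤ 3 days** for CYP2D6 inhibitors (the antidepressant stitching rule,
  applied to all inhibitors since most are antidepressants; configurable
  per drug class).

The episode end is the latest imputed end among constituents (union
semantics; identical to "the last prescription's end" unless supplies nest).
Stitching is idempotent and order-invariant, and is verified against a
brute-force day-set union oracle.

Concomitancy requires at least 3 consecutive days of overlap between an
inhibitor episode and the opioid assessment window; the window used is the
follow-up window (index date to follow-up end), since the phenoconverted
phenotype should describe metabolism during outcome ascertainment. When both
strong and moderate inhibitors qualify, the strong factor (the minimum)
wins. A person is *inhibitor-free* when no inhibitor episode intersects
[opioid start − 180 days, study end]; the 180-day washout boundary is read
inclusively (an episode ending exactly 180 days before the start disquali-
fies). Persons with several opioids contribute their earliest episode only
(same-day ties break alphabetically by drug, deterministically).

## Cohort and outcome

Index date = opioid start + 3 days; follow-up ends at the earlier of
index + 60 days and the opioid episode end. Inclusion: age ≥ 18, a first
opioid episode supplying ≥ 7 days, a determinate consensus genotype.
Exclusion: any cancer-coded encounter in the 180 days before index ("6
months" is operationalized as 180 days everywhere). Every filter's remaining
count is logged (attrition).

The outcome is the first encounter in the ED setting carrying a configured
pain diagnosis code within [index, follow-up end]; pain codes seen outside
the ED, or outside the window, do not count. The shipped pain/cancer code
lists are small illustrative ICD-10-like sets — real deployments supply
their own vocabularies.

24 baseline characteristics are assessed over [index − 180, index − 1]:
age, sex, race/ethnicity (one characteristic, two indicator columns),
7 pain-diagnosis flags, 7 comorbidity flags, 5 medication-history flags,
opioid dose (MME/day, carried as a numeric covariate, never computed), and
a prior-ED-visit count.

Three contrasts are labelled per row: **A** (primary) phenoconverted IM/PM
vs phenoconverted NM/UM over everyone; **B** inhibitor-exposed vs
inhibitor-free, restricted to genotypic NMs (no genetic impairment, so the
contrast isolates the drug interaction); **C** genotypic IM/PM vs NM/UM,
restricted to inhibitor-free persons (isolating genotype). Persons with an
inhibitor prescription but no qualifying 3-day overlap are not
phenoconverted in A and are excluded from B's comparison arm (which requires
inhibitor-freedom). Drug subgroups: hydrocodone/tramadol/codeine combined,
and oxycodone alone.

## Estimation

The propensity score P(exposed | x) is fit by maximum-likelihood logistic
regression on all 24 characteristics as main effects, using hand-rolled
IRLS (convergence when the largest coefficient change < 1e-8, cap 100
iterations; coefficients diverging past |30| flag separation with a
warning; rank-deficient designs raise naming the collinear columns). The
implementation is cross-checked against an independent GLM fit in the test
suite.

ATE weights are 1/p for the exposed and 1/(1−p) for the comparison group —
unstabilized and untruncated by default (truncation is available for
sensitivity analyses). Balance is the standardized mean difference
|m̄₁ − m̄₀| / √((v₁+v₂)/2), with weighted moments after weighting and
Bernoulli p(1−p) variance for binary covariates; SMD < 0.1 counts as
balanced. Zero pooled variance with unequal means reports +∞.

The effect estimate is exp(slope) from a weighted logistic regression of
outcome on exposure. Its 95% CI uses the heteroskedasticity-robust sandwich
variance A⁻¹BA⁻¹ with weights treated as known — the standard choice for
IPTW; treating the estimated propensity as fixed makes the interval mildly
conservative, which replicate studies here confirm (empirical coverage
≈ 95–96%, within the 93–97% band the test suite enforces at n = 5000 over
500 replicates). The unweighted OR is reported alongside.

The IPTW estimand is the population-averaged (marginal) OR: with correct
weighting, each weighted arm mean estimates the counterfactual population
event rate, so exp(slope) estimates odds(E[Y¹])/odds(E[Y⁰]). The generator
exposes exactly this quantity as ground truth (below), closing the loop
between estimator and estimand.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, with
every step seeded and fully deterministic (identical config + seed gives
byte-identical tables):

- **Genotypes** drawn under Hardy–Weinberg from a configurable allele pool;
  four pseudo-callers report the truth, a perturbed diplotype, or a no-call
  with per-tool rates.
- **Prescriptions**: 1–4 opioid refills with gap distribution straddling the
  14-day boundary; with configurable probability an inhibitor course placed
  to overlap the follow-up window by ≥3 days, by 1–2 days, or to sit in the
  washout only.
- **Covariates**: five confounders (depression, anxiety, benzodiazepine
  use, back pain, age) drawn conditionally on the exposure class, the
  remaining 19 as independent noise — so balance diagnostics should flag
  only true confounders. Binary confounders independent given exposure and
  a normal age with common variance make the implied true propensity model
  exactly logistic in main effects, i.e. the fitted model is correctly
  specified.
- **Outcomes**: logit p = α + τE + Σβⱼxⱼ. α is solved so the comparison
  arm's event rate equals the configured reference (default 1.8%); τ is
  solved by root-finding so the counterfactually standardized marginal OR
  over the analysis population equals the configured target. Calibration is
  performed on the persons who pass the inclusion filters, so the pipeline's
  cohort is exactly the population the truth refers to. Per-person
  counterfactual probabilities (p¹, p⁰) ship in the ground truth, and a
  Monte-Carlo standardization oracle over them is used as an independent
  check in the tests.

Shipped scenarios:

- **headline** — the study-condition defaults: comparison-arm rate 1.8%,
  true marginal OR 1.19, 15% inhibitor prescription exposure, allele
  frequencies placing roughly half the cohort in the phenoconverted IM/PM
  arm. Confounder effect sizes are conventions (no empirical covariate-
  outcome effects are available to copy): arm imbalances follow the
  published baseline table, with a small negative age-outcome coefficient
  so the net confounding is mild and slightly negative — matching a setting
  whose crude rate contrast (2.1% vs 1.8%) sits just below its weighted OR.
- **confounded** — same structure with large, unidirectional confounder
  imbalances and effects; the crude OR is markedly biased upward while the
  truth stays at 1.19. Used for parameter-recovery and balance testing.
- **inhibitor_only** — the effect attaches to inhibitor exposure (true
  marginal OR 1.49) on an all-functional genotype background, so everyone
  is a genotypic NM and the analysis-B contrast is isolated; inhibitor
  users carry more baseline depression/anxiety (most CYP2D6 inhibitors are
  antidepressants).

**What passing tests do not show.** The generator's codes are a toy
vocabulary; callers err independently (real callers share failure modes on
structural variants); one opioid and at most one inhibitor course per
person; no death/disenrollment censoring, no time-varying exposure, no
unmeasured confounding. Recovery of the calibrated OR therefore validates
the pipeline's logic and estimator, not the substantive clinical findings,
which require the original restricted-access data.

## Numerical choices and problem sizes

- IRLS tolerance 1e-8 / 100 iterations; calibration root-finding via Brent
  with xtol 1e-12 (achieved marginal OR matches the target to ~1e-9).
- Probabilities clipped to [1e-12, 1−1e-12] inside the logistic link.
- Dates are integer day offsets from an arbitrary epoch (2018-01-01),
  avoiding timezone and leap-second complications; intervals are inclusive
  of both endpoints everywhere.
- Validation problem sizes were chosen to keep each check's Monte-Carlo
  error far below its assertion band: golden-table and consensus oracles
  are exhaustive; stitching uses 1000 random record sets; parameter
  recovery runs the confounded scenario at n = 30 000; CI coverage uses
  500 replicates at n = 5000; the headline calibration check runs at
  n = 100 000. Replicate studies at n = 100 000 show the weighted-OR
  estimators unbiased with ≈ 4% sampling SD on the log-OR scale.

## Known limitations

- The 4-tablets/day assumption is applied uniformly, including to
  inhibitors; real sig data would replace it.
- The sandwich CI ignores propensity-estimation uncertainty (conservative);
  a seeded bootstrap would be the sensitivity alternative.
- The washout-boundary inclusivity and the 2–2 consensus split are
  conventions where the underlying definitions are silent; both are
  configurable and flagged in the configuration.
- Episode ends use union semantics; with strongly nested supplies this can
  exceed the literal "last prescription's end date".
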