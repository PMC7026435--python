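# Methods

## The staging model

The model stratifies adults with bipolar disorder into five ordered severity
stages from a single global severity score,

    severity = 10/12 · Σ (12 unit-interval profilers),

with four interior cutoffs at 1.70, 2.50, 4.50 and 6.10 (the 5th, 25th, 50th
and 75th percentile scores of the derivation cohort). The model's assumptions
are those of any equal-weight composite index: the twelve profilers are
exchangeable contributions to severity once normalised, and stage membership
is a deterministic function of the composite. The boundary convention is
lower-inclusive for stage 1 and upper-inclusive at each interior boundary
(stage *s* covers (c₍ₛ₋₁₎, cₛ]), which is the only convention consistent with
a published stage-5 threshold of "≥ 6.11" alongside a stage-4 boundary of
6.10 at one-decimal presentation. Full-precision scores use the same rule;
`assign_stages` implements it with a left-sided `searchsorted`, and the
formula is evaluated as `10·s/12` rather than `(10/12)·s` so the endpoints
0 and 10 are exact in floating point.

## Profiler transforms

The source publications report transformed means but not the transform
functions, so the transforms here are package defaults, each overridable via
the registry config (`data/default_transforms.yaml`):

| profiler | transform | default parameters | rationale |
|---|---|---|---|
| HospN, SuicAttN | capped count `min(x, cap)/cap` | cap 6, 6 | beyond ~6 lifetime events severity is saturated; caps reproduce the published transformed means from the published direct means to within 0.05 |
| IllnessN | capped count | cap 4 | same, narrower clinical range |
| ComPD, MetS, PD×BD | identity on {0, 1} | — | transformed means equal prevalences exactly |
| FAST total, leisure | linear rescale | /72, /6 | instrument ranges; 26.8/72 = 0.372 matches the published 0.37 |
| SCIP category | ordinal map | none 0, mild ⅓, moderate ⅔, severe 1 | equal spacing over four ordered levels |
| BMI | WHO step map | <25 → 0, 25–29.9 → 0.5, ≥30 → 1 | category-based cardiometabolic risk |
| SF-36 PF, MH | reversed linear clip on z | best +3, worst −3 | higher z is better health, so the map is decreasing; ±3 spans the norm-referenced range |

Known deviations of these defaults from the published transformed means, on
the cohorts the generator simulates: the equal-spaced SCIP map yields a
cohort mean near 0.41 where 0.47 was published (the original map was likely
steeper); the BMI step map on a mean-24.5/SD-4.9 cohort yields ≈ 0.30 where
0.15 was published (the original spread was likely narrower or the map
different). Both are recorded in tests as computed values, not tuned away.
Missing raw values propagate as NaN and severity is refused for incomplete
profiles, naming the profiler — silent zero-fill would bias severity downward.

## Cutoff calibration

`calibrate_cutoffs` re-derives cutoffs as empirical percentiles
(linear-interpolation definition, the most common convention) of a severity
sample, requiring ≥ 20 values and strictly increasing results; ties that
collapse boundaries raise, since the stages would no longer partition [0, 10].
Calibration is an explicit user operation because the sample underlying the
original percentile values is not recoverable.

## Construct-validity battery

Continuous profilers (and the GAF external validator) are compared across
stages by classical one-way ANOVA (dfs k−1, N−k); categorical profilers and
drug-pattern columns by Pearson chi-square without continuity correction,
using the asymptotic reference distribution regardless of small expected
counts (a warning is attached when any expected count is below 5, and
zero-marginal rows/columns are dropped with a warning). Tukey HSD uses the
studentized-range criticals from statsmodels. Raw p-values are reported with
no multiple-testing correction; the report header says so.

The monotone-worsening flag is a trend descriptor on the stage means of the
*transformed* profiler (so "worse" points the same way for every profiler,
GAF negated): a profiler is flagged when the last stage mean exceeds the
first and no adjacent improvement exceeds 25% of the range of the stage
means. The 25% tolerance separates profilers with a strong worsening trend
but one noisy early-stage inversion (e.g. hospitalisations, whose stage-2
mean sits below stage 1) from profilers with no net trend (the SF-36
mental-health scale, whose final stage is *better* than its first), without
being sensitive to small-sample jitter in five-group means.

Stage sample sizes printed alongside published percentage tables are
internally inconsistent in places; wherever a published statistic is
recomputed, denominators are taken as explicit inputs implied by the printed
percentages rather than inferred from table headers. With those denominators
three of the four anchor chi-squares reproduce to the printed precision; the
benzodiazepine statistic recomputes to 13.433 against a printed 13.430, the
attainable agreement given rounded percentages.

## Longitudinal analysis

Stage pairs are tabulated into a 5×5 count matrix with row-conditional
frequencies and exact aggregate fractions over |shift| ∈ {0, 1, ≥2} and
direction. The large-shift expectation check passes when at most 10% of
patients move two or more stages. Life-domain composites for the paired
tests are the mean of each domain's transformed profilers — an operational
choice, since the "dimensions" tested in the source analyses are not defined
there; it uses only model-internal quantities. Paired t-tests run separately
for the remained-same and regressed subsets of the sustained-euthymia
subgroup; subsets under two patients are skipped with a note, and an
all-zero difference vector returns t = 0, p = 1 rather than NaN.

## Synthetic cohort generator

The generator emulates the validation cohort the model was tested on:
129 completers of a 224-patient, 3-year follow-up. Defaults (the study
conditions, fixed once):

- **Baseline stage mix** 10.9 / 15.5 / 47.3 / 18.6 / 7.8% — the follow-up
  classification proportions, used as a stand-in because baseline proportions
  for the completers were not published.
- **Per-stage profiler distributions** matched to the published stage-wise
  means/SDs and prevalences: negative binomial for overdispersed counts
  (Poisson when the printed SD ≤ mean, e.g. stage-1 hospitalisations 0.7
  (0.3), where a negative binomial is undefined); truncated normals for BMI
  (12–60), FAST (0–72, 0–6, rounded to integers) and GAF (1–100); plain
  normals for SF-36 z-scores; Bernoulli for flags. The stage-3 personality-
  disorder prevalence uses the printed count over the stage size (27/61),
  as the printed percentage (14.8) is inconsistent with both. Cognition
  categories per stage use the printed "no impairment" share, splitting the
  remainder in the cohort-level mild/moderate/severe mix (19.4/20.9/20.2).
- **Transition kernel** built from the published row-wise shift percentages,
  rows renormalised. The stage-3 statement "18.2% regressed or progressed
  one stage" is read as 18.2% in *each* direction. Sustained-euthymia
  patients (probability 0.322) instead move by a shift distribution
  {−2: 5.3%, −1: 23.7%, 0: 55.3%, +1: 15.8%}, clipped to valid stages and
  renormalised — the published euthymic-subgroup breakdown.
- **Retention** 0.576, missing-completely-at-random by default (the study
  reported no severity difference between followed and lost patients);
  `dropout_severity_slope` adds a logit-linear severity dependence for
  sensitivity analyses.
- **Label consistency** is enforced by rejection sampling: a patient's
  profile is redrawn (vectorised, up to 1,000 rounds) until its computed
  severity falls in the intended stage's interval, so the scoring pipeline
  recovers the generator's stage for every patient. Typical acceptance is
  high because each stage's distribution parameters already centre severity
  inside the stage's interval; rejection mainly trims the overlap tails.
  With rejection off, intended-vs-assigned confusion concentrates on
  adjacent stages.

What the generator does *not* emulate: item-level psychometrics, laboratory
values, medication dosing, correlations between profilers beyond those
induced by the shared stage (within a stage, profilers are drawn
independently), and real attrition mechanisms. Passing tests on these
cohorts therefore demonstrate the pipeline's correctness and the model's
internal coherence under the published stage structure — not clinical
validity on new patient data.

## Problem sizes and numerical choices

Tests run on seeded cohorts of 129–2,000 patients; the Monte-Carlo kernel-
recovery check uses 10,000 baseline patients and three-binomial-SE bands on
the non-euthymic rows (the euthymic subgroup follows its own kernel by
design). Property tests (hypothesis, derandomised) cover transform ranges
and monotonicity, the stage partition on fine severity grids, severity
linearity and permutation invariance, and transition-matrix count
conservation and reversal symmetry. Statistical routines are cross-checked
against explicit brute-force oracles (double-loop O/E summation, SSB/SSW
mean-square ratio, one-sample t on differences) on ~1,000 random inputs.

## Known limitations

- The original transform functions and the derivation-cohort severity sample
  are unpublished; defaults here approximately reproduce the published
  transformed means, with the SCIP and BMI deviations noted above.
- Published tables carry internal inconsistencies (stage-5 n of 9 vs 10,
  ComPD stage-3 percentage, FAST leisure baseline SD exceeding the subscale
  range); the package adopts the follow-up stage counts 14/20/61/24/10 and
  count-implied prevalences and documents each choice rather than resolving
  them.
- Stage-wise ANOVA assumes homoscedastic normal groups; several published
  profiler rows note significant variance heterogeneity, and no Welch
  correction is applied, to mirror the original analysis.
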