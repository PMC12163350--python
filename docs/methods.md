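# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## The setting

A census establishment survey: every unit on the frame (N = 1022 HIV care
facilities by default) is solicited, so each carries base weight 1 and all
uncertainty in respondent-based estimates comes from nonresponse, not
sampling. Nonrespondents to the long "full" instrument are offered an
abbreviated web NRFU instrument sharing 35 analytic items (34 binary, one
continuous annual patient load). Administrative covariates — Ryan White
HIV/AIDS Program funding overall and Parts A–F, HPSA and MUA/P designations,
a collapsed Rural-Urban Continuum Code (metro 1–3 distinct, nonmetro 4–9 as
one category), and a record-abstraction count — are known for every frame
unit and drive both the weighting and imputation stages.

## Synthetic generator

The generator makes the response mechanism explicit so that downstream
stages can be validated against known truth.

* **Frame.** Ryan White cross-class populations default to 94 / 175 / 171 /
  582 (funded with Parts A and F; Part A only; Part F only; unfunded),
  reconstructed as respondent-count × final-weight from the published
  weight distribution; they sum to 1022 exactly. Contact-information
  completeness defaults to 960 complete / 58 partial / 4 missing, scaled by
  largest remainder for other frame sizes. The remaining covariates (Parts
  B/C/D, HPSA, MUA, RUCC, abstraction counts, 23 project areas) are drawn
  from plausible independent marginals; they carry no response effect by
  default and exist to give the covariate screen something to reject.
* **Response mechanism.** Full-survey completion is Bernoulli with a
  logistic propensity in rw_any, rw_a, rw_f. The four cell probabilities
  are exactly identified from the class response rates implied by the
  published weight distribution (96/175, 67/171, 198/582), with the
  all-respondent cell smoothed to 0.97 because a logistic model cannot
  produce probability 1. Expected full completes are therefore ≈451 rather
  than exactly 455; NRFU take-up (0.1048) and the access-without-response
  rate (0.067) are set so expected NRFU completes ≈59 and noncooperations
  ≈34. Facilities missing all contact information never respond. The
  mechanism is missing-at-random given the three funding covariates by
  construction, which is precisely the condition the weighting class
  adjustment corrects exactly in expectation.
* **Items.** The default instrument is a scaled-down dictionary of 40
  analytic items — the 35 shared NRFU items plus 5 full-only binaries —
  rather than the survey's 155/36; this keeps a full pipeline run at a few
  seconds while preserving every structural feature (shared vs full-only
  items, a continuous item, item-level missingness at 5%). Four binary
  prevalences are pinned to published full-survey estimates (77.03, 31.54,
  2.65, 2.44 percent); the rest default to 0.5. Every binary item carries a
  1.0 log-odds effect on one of the three funding covariates (cycled), and
  the intercept is re-solved numerically per frame draw so the *population*
  prevalence equals the configured target despite the covariate effects.
  This makes nonresponse informative for every item — the hard case for
  weighting — while keeping marginal prevalences interpretable. Patient
  load is log-normal (meanlog 4.3, sdlog 0.9) with log-scale shifts for
  funded facilities; no distribution is published for it, so this is a
  field-plausible choice (median ≈ 74 patients, long right tail).
* **What it does not emulate.** Recruitment timing, mode-choice behaviour,
  skip patterns, within-facility respondent selection, and any
  non-ignorable (MNAR) response. Passing tests therefore demonstrate that
  the estimators do what their theory promises under a correctly specified
  MAR mechanism — not that the real survey's nonresponse was ignorable.

One `numpy` Generator seeded from a single integer drives every draw;
identical seed and configuration give byte-identical CSV output.

## Status codes and rates

Four mutually exclusive groups partition the frame. A break-off (accessed,
some valid responses, no complete flag) counts as an attempter but not a
complete: it is grouped under noncooperation with a `full_partial` /
`nrfu_partial` detail code. The cooperation denominator is the shared
attempter count, so the three group rates are directly comparable and
`response = contact × cooperation` holds exactly on the unrounded values.
Rates are stored unrounded; one-decimal display rounding is left to the
report layer (the published combined response rate appears both as 51 and
50.3 depending on where rounding happened; the pipeline keeps 0.50293…).

## Nonresponse bias analysis

Binary contrasts use the difference of proportions with unpooled Wald
variance and a two-sided normal p; the continuous item uses Welch's
unpooled difference of means. This choice reproduces the published SEs on
reconstructed counts (e.g. 4.14 for the physician-availability item) to the
printed precision. Items are analysed complete-case, so n varies by item.
Familywise control defaults to α = .05 over a family of m = 35; m may
exceed the number of tests actually run (items skipped for missingness
still count), which is why the Bonferroni/Holm step is implemented directly
rather than delegated to a library routine that pins m to the vector
length. Bonferroni flags p < α/m; Holm steps down through α/(m−k).
Bonferroni rejections are a subset of Holm rejections by construction.

**Known limitation.** Wald proportion tests are anti-conservative deep in
the tail when one group is small and unbalanced (e.g. 59 vs 450 at low
prevalence), so at such sizes the realized familywise error can exceed α
even under Bonferroni. The familywise property is therefore validated where
the per-test level premise holds (balanced moderate groups); for
survey-sized unbalanced comparisons the adjusted threshold should be read
as approximate.

## Weighting

Backward elimination fits a logistic response-propensity model
(statsmodels, Wald p-values, main effects only; RUCC entered as a single
ordinal score) and repeatedly removes the covariate with the largest
p > .05. Fit failures (separation, non-convergence) drop the most recently
retained covariate with a warning rather than aborting. The abstraction
count is excluded from the candidate set by default, mirroring its lack of
association with reported patient load; a flag re-includes it. Note that at
per-test α = .05 each pure-noise covariate survives the screen with
probability ≈ .05, so occasional retention of a noise covariate is the
expected behaviour of the procedure, not a defect; the test suite asserts
the retention rate, not zero retention.

Class adjustment inflates respondent weights by N_c/r_c within each
cross-class of the selected covariates; final weights of nonrespondents are
0 and the respondent weights sum to N (machine precision). A populated cell
with no respondents is collapsed by truncating its class key — dropping
class variables from the end of the list — and merging it with every cell
sharing the shorter prefix, repeating (ultimately to a single frame-wide
cell) until every cell has a respondent. With an empty class-variable list
the whole frame is one cell, which also covers the degenerate full-response
case where the propensity model cannot be fit.

UWE = n·Σw²/(Σw)² over the n positive weights (≥ 1 by Cauchy–Schwarz,
equality iff constant); effective n = n/UWE. On the published four-point
weight distribution this gives 1.1153 and ≈408 of 455.

## Imputation

**Classes.** Per item, a CART tree (scikit-learn; Gini for binary,
variance for continuous targets) is grown on the donors over the ten
administrative predictors with `min_samples_leaf = 25` and a split
admission threshold of 2% of root impurity — large enough that a no-signal
target stays a single node at n ≈ 500, small enough that the generator's
1.0 log-odds effects are found. The tree is deterministic given the data;
exact split ties are broken by a fixed random state rather than by
predictor order. Imputation classes are terminal node × Ryan White funding.
If a class contains recipients but no donors, the minimum node size is
doubled and the tree regrown (escalating to the single-node tree); a
recipient stratum with no donors at all is a hard error.

**Allocation.** The weighted sequential hot deck is the deterministic
cumulative-allocation scheme: donors and recipients are sorted (Part A,
Part F, patient load ascending; missing sort values last; ties by facility
id), donor weights are rescaled to the recipients' total, and each
recipient is served by the donor whose cumulative interval contains the
recipient's cumulative start point. With unit recipient weights each
donor's usage count lies in {⌊e_d⌋, ⌈e_d⌉} of its rescaled allocation e_d;
with unequal recipient weights the served recipient weight differs from
e_d by less than the largest recipient weight. No randomness: identical
inputs give identical imputations.

**Cascade.** Step 1 fills item missingness among full respondents from
full-respondent donors; step 2 fills NRFU respondents — shared items from
the pooled full+NRFU donors, full-only items from full donors; step 3 fills
every item of the total nonrespondents from the now-complete respondent
pool. Donor weights are the final nonresponse-adjusted weights for
full-survey donors and 1 for all other donors; recipients weigh 1. Two
readings of the donor-weight rule were possible; this one (respondent
weights where they exist, 1 elsewhere) is adopted and documented rather
than asserted. In steps 1–2 donors must hold genuinely observed values;
step 3 deliberately donates previously imputed values, as the cascade
definition requires. Observed cells are never overwritten at any step.
An optional grouped-vector mode imputes a declared block of items jointly
from one donor (donors must have the whole block observed), which is how
skip-pattern families retain internal consistency; the default instrument
has no skip patterns, so per-variable trees in dictionary order are the
default.

## Weighted vs imputed estimates

The weighted route is the Hájek ratio mean with the with-replacement
Taylor-linearized variance, weights treated as fixed:
Var ≈ n/(n−1) · Σ wᵢ²(yᵢ−ȳ_w)² / (Σw)². The imputed route treats the
1022-row imputed dataset as observed equal-weight data (SRS formulas) —
deliberately naive, since that is how such datasets get used downstream.
The contrast SE adds the two variances as if independent; the datasets
overlap (respondents appear in both), so true contrast uncertainty is
smaller and the p-values are conservative. On the default run no item's
contrast reaches p < .05 and the imputed/weighted SE ratio averages ≈0.63:
the imputed dataset has ~2.2× the records and no weight variability, and a
single imputation ignores imputation uncertainty. This ratio is reported,
not asserted beyond being < 1: it is the method's known variance
understatement, and the reason the weighted dataset is the conservative
choice for facility-level analysis.

## Problem sizes in the test suite

Replicate-based properties use sizes chosen to estimate each quantity with
comfortable Monte Carlo margins: 500 replicates for the response-fraction
check (2 MC SEs), 200 for weighting parameter recovery and covariate-screen
retention rates, 2000 families for the null familywise simulation, 500
random classes for the hot-deck oracle, and 6 full-cascade replicates for
the imputed-vs-weighted prevalence tracking check (each cascade imputes 40
items × 3 steps). All stochastic tests run under fixed seeds.
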