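# Methods

## Problem and model

When a clinical prediction model built by logistic regression is taken to
a new cohort, the concordance statistic (c-statistic, equal to the area
under the ROC curve for a binary outcome) usually changes.  Two distinct
mechanisms drive the change:

1. **Case-mix**: the spread of the linear predictor
   lp = α + Xβ in the new population.  A narrower risk distribution
   lowers the achievable c-statistic even if every coefficient is exactly
   right; a wider one raises it.
2. **Coefficient validity**: the development coefficients β_D may simply
   be wrong for the new population.

`transportc` computes the panel of quantities that disentangle the two
for a development cohort D and validation cohort V:

- c^D — apparent c-statistic of the development fit on D;
- c^V — c-statistic of the development fit's predictions on V;
- SD(lp_D), SD(lp_V) with lp_D = X_D β̂_D and lp_V = X_V β̂_D, and their
  ratio SD(lp_V)/SD(lp_D).  Ratios below 1 indicate a more homogeneous
  validation case-mix (sample SD, denominator n−1; at the sample sizes of
  interest the n vs n−1 distinction is immaterial);
- the model-based c-statistic (mbc): the c-statistic expected in V's
  case-mix *if the model's predicted probabilities were exactly correct*.
  Estimated by replicating every validation subject `n_reps` times,
  drawing outcomes y* ~ Bernoulli(p̂_i), and taking the pooled c-statistic
  of the replicated p̂ against y* over all n·n_reps pseudo-subjects.
  Pooling (rather than averaging per-repetition c-statistics) is the
  lower-variance estimator of the expected concordance and is the
  definition implemented here.  `n_reps` defaults to 100, the minimum for
  a stable estimate; raising it shrinks the Monte-Carlo error at linear
  cost.  A gap mbc − c^V > 0 means the observed discrimination falls
  short of what the model's own probabilities promise in that case-mix,
  i.e. invalid coefficients;
- the refitted c-statistic c^refitted: the apparent c-statistic of the
  same specification re-estimated on V — the discrimination ceiling in
  that case-mix.  For a univariable model whose refitted slope shares the
  sign of the development slope, c^refitted equals c^V exactly, because
  the c-statistic is rank-based; the benchmark becomes informative with
  two or more predictors;
- the permutation test of homogeneity: pool the n_D + n_V subjects,
  reassign them at random into sets of the original sizes, refit on the
  permuted development set and score on the permuted validation set, k
  times (default k = 1000).  The p-value is the plain proportion of
  permuted c-statistics *strictly below* c^V — one-sided, no +1/(k+1)
  smoothing — so p = 0.00 and p = 1.00 are legitimate outcomes.  The null
  is rejected when p < α (default 0.05).

## Fitting and numerical choices

Models are fitted by Newton/IRLS maximum likelihood with an L2 penalty of
1e-6 on the slopes only, never the intercept.  The penalty exists solely
to keep estimates finite under complete or quasi-separation, which occurs
occasionally at n = 40 with a true slope of 3; it is far below any level
that would move the rank- and spread-based quantities computed from the
fit.  The solver caps at 100 iterations and flags `converged=False` when
the cap is hit (under separation the last finite iterate is returned; its
linear predictor still ranks subjects correctly, which is all the
downstream metrics use).  Iteration stops when the largest Newton step
falls below 1e-10.  Covariates are used raw — no centering or scaling.
The fitted model always includes an intercept, the standard choice for a
prediction model, even though the simulation generator below has none.

Degenerate inputs are handled explicitly rather than silently:

- all-0 or all-1 outcomes raise a typed error (fit and c-statistic);
- rank-deficient designs raise a collinearity error;
- a permuted split whose development or validation side has single-class
  outcomes is redrawn (and counted; a warning fires if more than 1% of
  rounds redraw).  Dropping such rounds instead would bias p toward 0 or
  1.  The same redraw-and-count rule applies to generated replicate pairs
  in the simulation engine;
- ties in scores receive half-credit via midranks (Mann–Whitney
  identity), so the O(n log n) c-statistic agrees exactly with pairwise
  enumeration;
- an exactly constant linear predictor yields SD 0 and an undefined (NaN)
  SD ratio with a warning.

## The simulation engine

The generator emulates the simplest setting in which case-mix and
coefficient validity can be varied independently: one standard-normal-ish
predictor, no intercept, x_j ~ N(0, σ_j²), y_j ~ Bernoulli(expit(β_j x_j))
with (σ, β) set separately for the development (j = D) and validation
(j = V) samples.  Three canonical scenario rows —

| scenario | σ_D | σ_V | β_D | β_V |
|---|---|---|---|---|
| Homogeneous populations | 1 | 1 | 3 | 3 |
| Different case-mix & predictor effects | 1 | 1.5 | 3 | 2 |
| Different case-mix & same predictor effects | 1 | 0.75 | 3 | 3 |

— crossed with per-sample sizes n ∈ {40, 100, 200} give nine cells.  The
symmetric predictor and absent intercept put the event rate at 50%
everywhere, i.e. roughly 20/50/100 events per fitted variable.  Each
replicate draws a fresh development/validation pair, fits on the
development sample and computes the full metric panel; a study aggregates
medians, interquartile ranges and the permutation rejection proportion.

What the generator does *not* emulate: multiple (correlated) predictors,
non-normal or skewed linear-predictor distributions (where the SD is a
poor case-mix summary), miscalibrated intercepts, non-50% prevalence, and
measurement error.  Passing tests therefore demonstrate the behaviour of
the measures under clean univariable case-mix/coefficient shifts, not
their behaviour on messy clinical data.

Seeding: a single master seed feeds a `numpy` `SeedSequence`; each
replicate runs on its own spawned child stream, so replicate r is
bit-reproducible in isolation and studies parallelize trivially.  All
randomness in a validation run (mbc resimulation, permutations) flows
from one generator.

## Problem sizes used in the shipped checks

The full design (1000 replicates × k = 1000 permutations × 9 cells) is
larger than routine test runs warrant, so the package's own checks use:

- metric medians: all nine cells at the full 1000 replicates with the
  permutation test off (the medians do not involve it);
- rejection proportions: the five informative cells at 250–300 replicates
  × k = 500 (200 replicates for the n = 200 cell).  The binomial
  Monte-Carlo standard error at these sizes is 1.3–3.5 percentage points,
  and assertions allow for it explicitly on top of each reference
  tolerance.

## Design choices that were genuinely open

- **Which coefficients the mbc uses.**  The mbc is defined as the
  expected c-statistic *given the prediction model is correct*, so it is
  computed from the development-fitted model's predicted probabilities on
  validation covariates.  (Descriptions that instead attach
  validation-refitted coefficients to the mbc conflict with that
  definition; with refitted coefficients the mbc would collapse toward
  c^refitted and lose its diagnostic role.)
- **Signed vs absolute mbc − c^V gap.**  At n = 40 the per-replicate
  absolute gap is dominated by the sampling noise of c^V (median ≈ 0.037
  even under perfect homogeneity), so the decomposition checks use the
  median of the signed gap, which is ≈ 0 when coefficients are valid and
  ≈ +0.04 when they are not.
- **Size-preserving permutations.**  Reassigning pooled subjects into
  sets of the original sizes n_D and n_V keeps every permuted c-statistic
  comparable to c^V; any other split would change the variance of the
  reference distribution.
- **Redraw rule** for degenerate permuted splits and generated pairs, as
  above.

## Known limitations

- Calibration is not assessed; the package addresses discrimination only.
- The refitted benchmark is uninformative for univariable models (exact
  rank identity with c^V).
- The SD of the linear predictor summarizes case-mix in one number and
  can mislead when the lp distribution is strongly skewed.
- The permutation test itself — as the simulation engine demonstrates —
  conflates case-mix and coefficient validity: it rejects at roughly the
  nominal rate when coefficients are wrong but the validation case-mix is
  wider (≈1–3% at α = 0.05), and rejects increasingly often (18% → 39%
  as n grows 40 → 200) under a pure, harmless case-mix narrowing.  The
  package reports it alongside the benchmarks precisely so users can see
  the disagreement.
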