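# Methods

## Design under validation

A two-wave cohort measures a 9-item depression screener (4-level items,
coded 0–3) at both waves, but the ninth item — suicidal ideation,
dichotomized as positive at "several days" or more (code ≥ 1) — is
treated as if it had been removed from the wave-2 questionnaire. The
tables are appended into long format (one row per participant per wave),
the wave-2 ideation cells are set to missing with the truth held out, and
the item is multiply imputed from conditionals learned at wave 1. The
pipeline then asks two questions: how accurately are the held-out values
recovered (confusion-matrix diagnostics pooled over the m imputations),
and do adjusted associations with related constructs (smoking status,
sleep-duration category) survive the substitution of imputed for true
exposure (Rubin-pooled multinomial models, 95% CI overlap against the
self-report benchmark)?

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions every downstream claim is made under.

**Latent structure.** Each participant carries a latent depression
severity per wave; the two wave values are bivariate standard normal with
correlation `cross_wave_rho` (default 0.6, a plausible 3-year test–retest
correlation for a trait-like severity), plus small additive shifts from
demographic categories (default: +0.10 for women, +0.15 for the youngest
age group). Item j's response at a wave is `loading_j * severity + noise`
(unit normal noise), cut at the item's strictly increasing thresholds —
the standard graded-response construction, the minimal model giving
correlated ordinal items with a controllable rare category. PTSD,
physical-functioning and alcohol latents are correlated 0.5 / 0.3 / 0.3
with the depression latent and drive their own item sets (17 five-level,
10 three-level, 5 binary items respectively). The DSM-IV "sensitive" PTSD
screen requires "moderately"+ (code ≥ 2) on ≥ 1 intrusion, ≥ 3 avoidance
and ≥ 2 hyperarousal items, with the conventional 5/7/5 cluster split in
instrument order.

**Calibration.** The ninth item's first threshold defaults to 2.527,
which puts the dichotomized wave-2 prevalence at the target 4.05% under
the default latent structure; `calibrate_ideation_threshold` re-derives
it for any parameterization by bisecting the empirical margin of the
item's latent response (200,000 draws, tolerance ±0.1 percentage points
by default). Item 4 ("feeling tired") defaults to ~43% endorsement, so
the alternate-target experiment contrasts a rare and a common item on the
same cohort. The default first cuts of the remaining items span
endorsement rates of roughly 23–41%.

**Outcomes.** Smoking (never/former/current) and sleep category
(≤5 / 6 / 7–9 / ≥10 hours) are drawn per wave from baseline-category
logit models whose intercepts reproduce configured marginal
distributions (defaults 59.3/26.8/13.9% and 18.2/33.0/46.5/2.4%) and
whose ideation coefficients are the logs of configured odds ratios
(defaults: former 1.23, current 1.87; ≤5 h 5.44, 6 h 2.08, ≥10 h 6.19).
Because the outcome model is known exactly, a maximum-likelihood refit on
generated truth is an oracle for the association-recovery stage. Sleep
hours are drawn as integers consistent with the category; the imputation
models use the continuous hours, the analysis models the category.
Demographic coefficients in the outcome models default to zero, so the
adjustment set is innocuous by construction; they are configurable for
confounded scenarios.

**What the generator does not emulate.** Attrition and enrollment
design, survey weighting, measurement drift between waves, differential
item functioning across demographic groups, and any misfit of the
graded-response model itself. Passing tests therefore show that the
pipeline recovers structure *of this kind*; they do not certify behaviour
on a real cohort, where the conditional distribution of the target may
shift between waves.

## Imputation engine

`fit_fcs` is a from-scratch chained-equations engine. Per imputation
(independent seed stream spawned from the master seed, so runs are
reproducible and parallelizable): missing cells are initialized by draws
from the observed margins; each burn-in cycle visits the incomplete
variables in the configured sequence, refits the variable's univariate
model on the currently complete data and redraws its missing cells; the
final cycle's values are kept.

* **Categorical (discriminant) imputer.** Linear-discriminant class
  posteriors: proportional priors, class means and pooled within-class
  covariance of the predictor scores (ordinal and binary predictors enter
  as numeric codes, nominal ones as treatment-coded indicators,
  continuous as-is). A ridge of 1e−6 is added to the covariance diagonal
  and the discriminant is computed on the reduced-rank eigenbasis
  (relative tolerance 1e−10), so near-collinear predictor sets — e.g. the
  PTSD composite together with its own 17 items — are handled without
  special-casing. Missing values are drawn from the posterior class
  probabilities. Parameter uncertainty is propagated by refitting on a
  bootstrap resample of the complete rows per imputation (approximate
  proper imputation); a rare class that drops out of a resample gets
  posterior mass zero for that imputation.
* **Continuous (Bayesian linear) imputer.** σ² drawn from
  SSR/χ²(n−rank), coefficients from N(β̂, σ²(X′X)⁻¹), then a predictive
  draw.

**Burn-in.** Default 10 cycles. In the validation design exactly one
variable is incomplete, so its conditional model depends on no imputed
value and the chain is converged after a single cycle; the engine detects
that case and skips the redundant cycles (mathematically exact, not an
approximation). Multivariate missingness uses the full cycling.

**Presets.** `PHQ-*` uses the 8 remaining depression items (4-level
categorical); `ALL-*` adds the five demographics, 10 physical-functioning
items, 17 PTSD items plus the composite screen, smoking, continuous sleep
duration and 5 alcohol items — 48 predictors. `*-BIN` models the
dichotomized target; `*-ORD` models the 4-level item, which is
dichotomized *after* imputation for all evaluation and analysis. `RAN`
draws i.i.d. Bernoulli at the observed prevalence — the uninformed floor
whose expected sensitivity equals its assignment rate.

## Pooling and evaluation

Rubin's rules: pooled point = mean of per-imputation estimates; total
variance `T = W + (1 + 1/m)B`; degrees of freedom by the classic
`(m−1)(1 + W/((1+1/m)B))²` formula (the small-sample correction is
negligible at m ≈ 100 and is intentionally not applied; B = 0 falls back
to the normal quantile). Associations are pooled on the log-odds scale
and exponentiated.

Diagnostics are computed per imputed dataset and pooled by averaging;
the across-imputation interval is the 2.5th–97.5th percentile by default,
with min–max also computed (printed diagnostic tables of this design do
not always state which convention their parentheses use, so both are
retained). Report rounding is half-up: integer percent for
sensitivity/specificity/PPV/NPV, two decimals for prevalence; full
precision is kept internally. A statistic with a zero denominator is
returned as NaN and flagged, never silently zeroed.

Multinomial association models are fit by maximum likelihood
(statsmodels `MNLogit`, Newton iterations, observed-information
covariance) on the target wave only, with treatment-coded covariates and
fixed reference levels (never-smoker; 7–9 h). Age enters as age-group
indicators, matching what the generator emits. A coefficient diverging
beyond |20| is reported as complete separation rather than returned; at
cohort sizes below ~1,500 the rare ≥10 h sleep category crossed with a 4%
exposure can genuinely produce empty cells, so small demonstration runs
should use n ≥ 2,000.

## Numerical and design choices

* Missingness is a single NaN sentinel; ordinal code 0 is a legal
  response and is never overloaded.
* Ordinal items are coded 0–3 (depression) and 0–4 (PTSD, "moderately"
  = 2): the conventional instrument codings.
* The printed sleep-category distribution used as a default sums to
  100.1% because its entries are rounded percentages; only ratios to the
  reference category enter the logit intercepts, so the excess cancels.
* CI overlap uses closed intervals: a shared endpoint counts as overlap.
* All randomness flows from numpy `SeedSequence` spawning: one master
  seed per experiment, one child stream per preset and per imputation.

## Problem sizes

The default experiment runs n = 5,000 participants with m = 20
imputations per preset — large enough that the preset ordering
(ordinal-target prevalence ≥ binary-target; every informed model far
above the random baseline) is stable across seeds, and small enough for
routine use. Baseline simulations and association-recovery refits use the
full n = 63,028 study scale, where a single generator call and
maximum-likelihood fit take seconds. Interval-coverage checks use 200
replicates of a reduced problem (n = 200, m = 10).

## Known limitations

* The discriminant imputer assumes homoscedastic-normal predictor scores
  within class; with ordinal predictors this is a working approximation
  (exactly the approximation the validated design relies on), and it can
  misestimate prevalence even when classification is reasonable.
* Proper-ness of the bootstrap-refit scheme is approximate; coverage is
  verified empirically (91–98%) rather than derived.
* No multilevel or joint-model imputation: rows of one participant are
  conditionally independent given the predictors in the univariate
  models. The long-format design carries the cross-wave information.
* Two waves only in v1; the wave label is open for extension.
* No survey weights, clustering or longitudinal GEE in the association
  models.
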