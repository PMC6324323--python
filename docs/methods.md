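# Methods

This note documents the models, conventions, and design choices behind
`icurisk`: what each pipeline stage computes, what the synthetic cohort
generator does and does not emulate, and the numerical decisions a
maintainer would otherwise have to reverse-engineer from the code.

## Cohort rules and windowing

A stay enters the cohort if the patient is an adult (age ≥ 18 y), the ICU
stay lasted at least 4 hours (boundary inclusive), and the stay is the
patient's first ICU admission (`icu_admit_rank == 1`, carried in the stay
table rather than recomputed from timestamps). All event times are hours
since ICU admission; the analysis window is the half-open interval
[0, 24) h, so an event stamped exactly 24.0 h is excluded — the half-open
convention avoids double-counting a boundary event and is a documented
choice, not an external requirement.

## Trajectory features

For each of V variables, eight per-patient summary measures over all
windowed observations: min, max, mean, sample (n−1) SD, first, last,
last−first, and the ordinary least-squares slope of value on time
(units/hour). Column order is variable-major, measure-minor, so matrices
have exactly 2V (baseline mode) or 8V (trajectory mode) columns.

Degenerate inputs: with a single observation, min/max/mean/first/last are
that value while SD, last−first, and slope are *missing*, not zero —
imputing "no change" would assert evidence that does not exist; the
missing cells are then median-imputed like any other. With zero
observations all eight are missing. First/last are ordered by ascending
time with ties broken by input order. Slopes are also missing when all
observation times coincide.

Imputation uses the median of each measure over the *training* rows only;
the learned medians are frozen and reapplied to test rows. A predictor
with no non-missing training value cannot be imputed; the pipeline drops
it (with a warning) and records the dropped name so test-time matrices
stay aligned.

## Text features

A patient's "note set" pools the tokens of all their first-24-h notes.
Tokens are lowercased maximal alphanumeric runs — so a phrase like
"pupils fixed" contributes the two single tokens `pupils` and `fixed`;
no stemming, stop-listing, or negation handling is applied. The
vocabulary is the k = 1000 most frequent terms by total training token
count (ties broken lexicographically; "most frequent" by token count
rather than document frequency is a documented choice). Weights use
sublinear term frequency with smoothed idf:

    w(t, d) = (1 + ln tf(t, d)) · idf(t),   idf(t) = ln((1+N)/(1+df(t))) + 1

Natural logarithms throughout (the base only rescales weights, which
standardization absorbs). The +1 smoothing keeps idf strictly positive
even for a term present in every training note set, so rarer terms always
receive strictly larger weights at equal tf. No vector length
normalization is applied: text and structured predictors are z-scored
jointly at fit time, which puts them on one scale for the ridge penalty.
Out-of-vocabulary tokens contribute nothing — in cross-site transfer a
test-site patient whose notes share no terms with the training site's
vocabulary gets a purely structured-data prediction.

## Ridge-logistic model

The fitted objective is the penalized log-likelihood
ℓ(β₀, β) = Σ yᵢηᵢ − log(1+e^{ηᵢ}) − (λ/2)‖β‖², with the intercept
unpenalized and the penalty defined on the z-standardized predictor
scale. Fitting is Newton/IRLS with step-halving (the objective is
monotone by construction); convergence requires the max-norm of the
penalized gradient to fall below `tol` (default 1e-8 standalone, 1e-6
inside the harness). Columns that are constant in training get unit
scale (their coefficient is exactly zero). Non-convergence raises an
error carrying the iteration count and gradient norm rather than
returning a silent partial fit.

λ is selected on a log-spaced grid (default 10⁻³…10³, 7 points) by
stratified inner cross-validation (default 5 folds) maximizing held-out
AUC under the **one-standard-error rule**: the chosen λ is the largest
grid value whose mean inner AUC is within one SE of the best. Plain
argmax is nearly undefined here — AUC is rank-based, and ridge shrinkage
often changes held-out rankings imperceptibly, so argmax degenerates into
a coin flip among statistically indistinguishable candidates. The one-SE
rule resolves those ties toward the more regularized (more stable) model,
the convention familiar from glmnet; it reduces to "ties go to larger λ"
when AUCs are exactly equal.

## Evaluation

* **AUC** — Mann–Whitney estimator, ties counted half.
* **AUPRC** — average-precision step form of the precision-recall curve
  (trapezoidal interpolation in PR space overstates area, so it is not
  used). Its chance level equals the outcome prevalence.
* **Modified Hosmer–Lemeshow** — rows sorted by predicted risk and cut
  into G = 10 equal-count groups, boundary ties falling to the lower
  group; C = Σ (O−E)²/(E(1−E/n_g)); degenerate groups (E = 0 or n_g) are
  merged with a warning. The reference distribution defaults to
  chi-square with **G** degrees of freedom, the correct calibration for
  externally supplied risks (out-of-fold or transfer predictions): under
  a correctly specified model the simulated mean of C is ≈ G, and G−2
  degrees of freedom would roughly double the nominal 5% rejection rate.
  `df=G-2`, the classical development-sample convention, is available by
  argument. P > .05 is read as adequate calibration.
* **Bootstrap CIs** — percentile bootstrap (B = 1000) of the mean of the
  R·K outer-fold AUCs. Two models differ significantly when each model's
  95% CI excludes the other's point estimate.
* **Cut point** — exhaustive search over observed scores maximizing
  Youden's J (default) or F1; reports sensitivity and PPV at the chosen
  threshold. The criterion is a documented default, offered both ways.
* **Model comparison** — Welch's (unequal-variance) unpaired t test on
  fold AUCs; fold-AUC variances genuinely differ across model modes.

## Validation harness

Pooled nested CV runs R repetitions (default 100) of stratified K-fold
(default 10) cross-validation; every fit-time artifact — imputation
medians, standardization means/SDs, vocabulary, idf, and λ — is refit
from scratch on each outer-training partition, so outer-fold AUCs are
honest. Stratified folds prevent single-class folds at ~10% prevalence.
Repetition and fold seeds derive from the master seed via numpy
`SeedSequence([master, repetition, fold])`, making the full harness
reproducible bit-for-bit. AUPRC, calibration, and cut-point metrics are
computed on the out-of-fold risks of the first repetition, where each
patient is scored exactly once by a model that never saw them. The inner
loop tunes λ only; vocabulary size is fixed. In pooled mode one
vocabulary is fitted on the pooled training corpus; in cross-site mode
each training site's own vocabulary and idf travel with its model.

The alive-at-24-h sensitivity analysis drops patients with a death time
before 24 h and reruns the full nested CV — meaningful because the
generator stops producing observations and notes at death.

## The synthetic cohort generator

The generator emulates the statistical structure the models assume, not
physiology. Per patient: a site (mixture weights, default three sites), a
mortality outcome (marginal prevalence 0.104, with per-site odds
multipliers renormalized to preserve the marginal), and for decedents a
death time that falls inside the 24-h window with probability 0.147.
Observation times are a homogeneous Poisson process per variable on
[0, min(24, death, discharge)) h; values follow

    value(t) = baseline + trend · t + noise,

with the per-patient baseline Gaussian around an outcome-shifted mean and
the per-patient trend Gaussian around the outcome-group mean. The default
panel has 24 labs/vitals; the GCS family carries the characteristic
trends (total: +0.124 points/h in survivors vs −0.034 in nonsurvivors),
and blood-gas/lactate variables carry elevated missingness (40–45% of
patients never measured). Notes are multinomial token draws over ~33
clinical terms — decompensation terms (sepsis, shock, pupils, fixed,
ecmo, …) upweighted in decedents, recovery terms (extubated, awake,
denies, pod, …) upweighted in survivors — plus a Zipf(1.15) "filler"
vocabulary of 1600 neutral types, rotated per site so that per-site top-k
vocabularies genuinely differ.

Free parameters the source conditions do not pin down were chosen once
and documented: sampling rates ~0.9–2/h for vitals and ~0.08–0.5/h for
labs; ~3 notes averaging ~55 tokens per patient; effect sizes (baseline
level shifts ~0.1–0.35 SD, trend heterogeneity comparable to the
between-group trend difference, term shifts ~0.25–0.75 log-odds) set so
that pooled discrimination lands in the regime multi-site ICU models
report (baseline AUC ≈ 0.8, trajectory ≈ 0.87–0.89, +NLP ≈ 0.91–0.94) —
realistic difficulty rather than trivially separable classes.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real EHR data: inter-variable correlation
(each variable is drawn independently given the outcome), hard
physiologic ranges (trajectories are unbounded Gaussians, so tails can
stray outside score limits; bounds are available per variable but off by
default because ceiling clipping biases slope recovery), informative
observation timing (sampling intensity is outcome-independent, while
real clinicians measure sicker patients more often), note grammar or
negation, and within-patient nonlinear dynamics. Results on this
generator validate the *pipeline machinery* — leakage-safety,
bookkeeping, estimator correctness, ordering of nested predictor
families — not clinical performance.

## Problem sizes

Analysis drivers and the acceptance script run at desk scale: cohorts of
500–20 000 synthetic patients, 3–24 variables, vocabularies of 40–1000
terms, and 5–100 CV repetitions depending on what each quantity needs
(marginal checks use the largest cohorts; the three-mode CV uses a
six-variable panel at n = 4000 with R = 5). These sizes are the package's
own choices for demonstrating each property with adequate Monte-Carlo
precision.

## Known limitations

* The 8-measure trajectory set is one reasonable reconstruction of
  "measures of distribution, variability, and trajectory"; other sets
  (IQR, time-weighted means, spline coefficients) are deliberately out of
  scope.
* Mean slopes among decedents are heavy-tailed: patients observed only
  briefly (early deaths, sparse labs) produce high-variance slope
  estimates, so group-mean comparisons need the Wilcoxon test or large n.
* The Hosmer–Lemeshow statistic on out-of-fold risks can reject for
  well-discriminating but shrunken models; ridge shrinkage trades
  calibration-in-the-small for variance, and no recalibration step is
  included.
* `select_lambda` assumes the grid brackets the optimum; it never
  extrapolates beyond the grid.
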