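# Methods

`bcaisd` implements a complete analysis pipeline for predicting the time to
breast-cancer onset (BCaO) in healthy women from lifestyle and health-history
questionnaires: synthetic cohort generation with a closed-form oracle,
missing-value imputation, censored-data feature selection, individual
survival distribution (ISD) models centred on multi-task logistic regression
(MTLR), censoring-aware evaluation, counterfactual lifestyle interventions,
and a cross-validated benchmark harness.  This note records the models, the
defaults and their rationale, the numerical choices, and the limits of what
the synthetic experiments can show.

## The synthetic cohort and its oracle

The cohort the pipeline targets is access-restricted, so `cohort_sim`
generates cohorts with the same statistical skeleton:

* **Schema.** 122 features in four questionnaire blocks — baseline (2),
  health and lifestyle (56), diet history (52), past-year physical activity
  (12) — of which 98 are *actionable* (diet, supplements, activity, social
  indices, smoking, anthropometrics) and 24 *intrinsic* (age, reproductive
  and medical history, demographics).  Each feature carries a dtype and an
  admissible range; marginals are clipped Gaussians for numeric features and
  fixed-probability draws for categorical ones.
* **Outcome model.** Weibull proportional hazards,
  `S(t|x) = exp(-(t/λ(x))^k)` with `λ(x) = λ0·exp(-xβ/k)`.  The Weibull was
  chosen because it provides a closed-form oracle for every test and nests
  the exponential; the shape default is k = 1.5 (mildly increasing hazard,
  appropriate for an ageing cohort).  The linear predictor uses standardized
  feature values.
* **Sparse risk vector.** Ten features carry risk by default, with the sign
  pattern of the published multivariable elastic-net selection: age (+,
  0.3007), selenium intake (−), social connection index (+), orange
  vegetables (−), fatty fish (−), menarche age (−), social sharing index
  (+), hormone-use history (+), whole grain (+), vitamin E (+).  Only the
  age magnitude is taken from the published coefficient table; that table's
  remaining magnitudes are specific to a cohort of 18k subjects with 605
  events and would be statistically invisible in simulations, so the other
  nine defaults use magnitudes 0.10–0.25, large enough that the sparse
  structure is identifiable at simulation scale while preserving every sign.
* **Censoring.** Administrative, uniform on [95, 207] months, independent of
  covariates — the observed pattern of a staggered-entry cohort with a fixed
  registry-linkage date, without modelling entry dates.
* **Calibration.** The baseline scale λ0 is tuned by bisection on the fixed
  latent draws until the realized event fraction is within 0.1 percentage
  points of the target (default 3.31%).  An unattainable target (e.g. at
  tiny n, where rates are quantized) raises with the closest attainable
  rate.
* **Missingness.** Whole-block dropout first (default: 8% of subjects for
  each of the diet and activity blocks, mirroring sub-study participation;
  the cohort is defined by completion of the health questionnaire, so that
  block is never dropped), then item-level holes (2%) — both completely at
  random, applied after outcome generation.  Real questionnaire missingness
  is plausibly informative; MCAR is a deliberate simplification.
* **Confounding hook.** A single latent "health-consciousness" factor can
  load on all numeric diet/supplement/activity features
  (`confounder_strength`, default 0) to reproduce qualitatively the
  unobserved-confounder narrative around supplement effects.

What passing tests do *not* show: robustness to informative missingness,
within-block correlation structure beyond the single confounder, calendar
effects, competing risks, or any claim about the restricted cohort's true
effect sizes.

## Preprocessing

Three imputers share a fit/transform contract so cross-validation folds
never leak:

* **Median** (mode for categorical features; ties broken by sorted category
  order).
* **KNN** (k = 2 by default): donors are rows with the target feature
  observed; distances are Euclidean over the remaining features — z-scored
  numerics and one-hot categoricals — averaged over co-observed coordinates
  and rescaled (the `nan_euclidean` convention).  Numeric targets get the
  donor mean, categorical targets the donor majority; distance ties resolve
  by donor row order.
* **MICE** (10 sweeps by default): median initialization, then column-order
  sweeps regressing each incomplete column on the current completion of all
  others — ordinary least squares for numeric targets, one-vs-rest linear
  scores with argmax for categorical.  Predictions are deterministic (no
  residual draws); a seed hook exists for stochastic variants.  The final
  sweep's per-column models are stored and replayed verbatim on held-out
  data.  A tiny ridge (1e-8, trace-scaled) keeps one-hot collinearity
  solvable; a genuinely singular design falls back to the median fill for
  that column.

Encoding expands a categorical feature with L observed levels into L
indicator columns and z-scores numeric columns with fitting-set mean and
population SD; the fitted transform is replayable on new data, with unseen
categories mapped to all-zero indicators (logged).

## Feature selection

Four censored-data selectors plus a passthrough arm, all pure functions of
(design matrix, outcome, config):

* **Univariate Cox** — per-column Cox fits, keep Wald p < 0.001.
* **RFE-Cox** — iteratively drop the covariate with the smallest |z| =
  |coef|/SE from the multivariable fit until 10 remain.  |z| is used as the
  importance because it is the Cox analogue of coefficient-magnitude RFE and
  is scale-free; singular fits retry with a small L2 stabilizer.
* **mRMR with concordance relevance** — relevance |C(f) − 0.5| (so
  protective and deleterious features score symmetrically), redundancy the
  mean |Pearson r| with the selected set, combined by the difference (MID)
  rule; greedy, ties broken by column order.
* **Elastic-net Cox** — a regularization path per l1-ratio (default grid
  0.1/0.5/0.9, 50 alphas, `alpha_min_ratio` 0.01), each (ratio, α) scored
  by internal-CV concordance of the linear risk score; the maximizer's
  coefficients are read from the warm-started path fit on the full fitting
  set (a cold single-α refit can diverge on near-separated folds).  Nonzero
  coefficients are the selection, reported signed and sorted by magnitude.

All internal Cox fits use a Newton–Raphson partial-likelihood solver with
**Breslow** tie handling, written in-package: month-resolution follow-up
produces many ties, and the solver must expose Wald standard errors, which
the available library implementations do not combine (one fits Efron ties
only, the other exposes no SEs).  The solver is validated against an
independent implementation on tie-free data, where the two tie conventions
coincide.  One-hot groups are penalized column-wise, not as groups.

## ISD models

**MTLR.**  Follow-up is discretized at m = ⌈√(#events)⌉ grid points placed
at event-time quantiles (quantile grids keep per-interval event counts
balanced).  A subject's outcome is the monotone binary sequence y with
y_j = 1 iff the event occurred by τ_j; the m+1 legal sequences receive
softmax probabilities of scores f(y,x) = Σ_j y_j(θ_j·x + b_j), computed
with a single reverse cumulative pass.  Uncensored subjects contribute the
probability of the interval containing their event time; censored subjects
marginalize over all sequences with the event after the *nearest* grid
point (a subject censored past an interval's midpoint counts as surviving
the whole interval — the actuarial convention; flooring every censoring
time to the previous grid point empties late risk sets under heavy late
censoring and biases the discrete hazard upward, visibly pulling the
bias-only model below the Kaplan–Meier curve near the horizon).  The objective adds (C/2)‖Θ‖² and a first-difference smoothness
penalty on adjacent time slices, and is minimized by L-BFGS from zero
initialization (deterministic) to gradient tolerance 1e-5.  Default
hyperparameter grid: C ∈ {0.01, 0.1, 1, 10}, smoothness ∈ {0, 0.1}.
Because the per-time weights are unconstrained, predicted curves of
different subjects may cross, and curves need not reach zero at the last
observed time — both verified by tests.

**Soft-L1-Hinge finetuning.**  After pre-training, the model can take
gradient steps on a differentiable surrogate of the L1-Hinge loss: the
point prediction is the expected survival time
t̂(x) = Σ_k S(τ_k|x)(τ_{k+1} − τ_k) (grid extended past τ_m by the final
spacing), uncensored subjects contribute a smoothed absolute error
√((t̂−t)² + ε²), censored subjects softplus(c − t̂).  The true training
L1-Hinge is tracked along the trajectory and the best iterate (possibly
the starting point) is returned, so finetuning can never worsen the
training metric; a tenfold surrogate blow-up aborts to the pre-training
parameters.  This surrogate is this package's own reading of a
"soft L1-Hinge" objective; other differentiable medians are possible.

**Baselines.**  Cox proportional hazards with a Breslow baseline cumulative
hazard (unpenalized with a 1e-3 L2 stabilizer for one-hot collinearity, or
elastic-net) and parametric AFT (Weibull, log-normal) fits produce the
comparison ISDs; their curves cannot cross, which the tests assert as the
structural contrast to MTLR.  Off-grid times are evaluated by linear
interpolation.  The benchmark roster names nine model slots — CoxPH,
CoxNet, AFT, RSF, GBCM, CW-GBCM, DeepHit, DSM, MTLR — with the
forest/boosting/deep slots left as registry adapters: any constructor with
the fit/predict-curves contract can be registered, and unregistered slots
produce explicit skip records in the grid.

## Evaluation

* **L1-Hinge** (months): |pred − t| for uncensored subjects,
  max(0, c − pred) for censored ones, averaged.  Predicted medians come
  from the 0.5-crossing of the ISD by linear interpolation; a curve that
  ends above 0.5 extends its final segment's slope (the tail rule), and a
  median that is still infinite is capped at 10× the maximum observed
  follow-up so means stay finite.  The cap is a pragmatic necessity of a
  bounded follow-up window with very low event rates.
* **Time-invariant C-index**: comparable pairs are (i, j) with t_i < t_j
  and subject i uncensored; concordant when the predicted medians are
  ordered the same way; tied predictions credit 0.5; exactly tied observed
  times are not comparable (Harrell conventions).
* **D-calibration**: p_i = Ŝ_i(t_i); B = 10 equal probability bins, upper
  edges closed (a p exactly on an edge falls in the lower bin); censored
  subjects spread weight max(0, min(p,u) − l)/p over bins [l,u) below p
  (their event probability is uniform on [0, p] under the model), with
  p = 0 assigned wholly to the lowest bin.  The statistic is the Pearson
  chi-square against the uniform n/B expectation with B − 1 degrees of
  freedom; "calibrated" means p > 0.05.  With fractional censored weights
  the chi-square reference is approximate; the type-I behaviour is checked
  empirically (the generator's true curves pass in ≥ 90% of replicates).
* **KM/Greenwood**: product-limit estimator with Greenwood variance and
  log(−log) confidence limits, validated against an independent
  implementation.  The Brier score is deliberately not part of the report:
  at ~97% censoring its clinical interpretability collapses.

## Harness

Outer 5-fold cross-validation stratified jointly on δ and T: within each
censoring class subjects are ranked by follow-up, cut into k quantile bins,
and each bin dealt round-robin (shuffled, seeded) across folds; bins
smaller than k merge with a neighbour.  Imputation, encoding, selection and
tuning are all fitted inside the training fold.  Hyperparameters are chosen
by internal 5-fold CV on each model family's native preference — L1-Hinge
for the discrete-time MTLR (whose loss targets individual times), C-index
for the Cox/AFT families (whose partial-likelihood objective is a ranking
criterion); single-point grids skip inner CV.  D-calibration is assessed
per fold, and the model-selection rule requires calibration in *every*
fold before comparing losses; ties within 1e-9 of the best mean L1-Hinge go
to the higher mean C-index.

## Counterfactuals

A counterfactual report edits exactly one *actionable* feature of one
subject on the raw questionnaire scale, replays the fitted
imputer → encoder → selection → model pipeline, and reports the change in
predicted median BCaO time (months), optionally converted to attained age
by `ceil(age + months/12)` (ceiling reproduces the published month→age
conversions).  Editing an intrinsic feature (age, menarche age,
hormone-use history …) is refused, and edits must stay inside the
feature's admissible range.  These are model counterfactuals under a
stable-covariate assumption — not causal estimates; unobserved confounders
(e.g. health-consciousness driving both supplement use and risk) can make
them misleading, which is exactly why the generator exposes a confounder
hook for sensitivity experiments.

## Problem sizes used in the test and acceptance suites

The property suites run at sizes chosen to make each statistical check
informative yet quick on a single CPU: calibration and KM-agreement checks
at n = 2000 over 20 seeds; sparse-structure recovery at n = 10,000 with a
10% event rate over 10 seeds (at the 3.31% default rate the check would
need the full 18k cohort to have comparable power); the end-to-end smoke
test at n = 1200 over 3 seeds with 5 MICE sweeps.  The full 135-entry grid
is audited by enumeration and exercised end-to-end on reduced rosters.

## Known limitations

* The D-calibration chi-square is approximate under fractional censored
  weights; p-values very near 0.05 should not be over-read.
* The soft-L1-Hinge surrogate is one reasonable differentiable proxy; its
  best-iterate guarantee applies to the training metric only.
* MICE is single-imputation with deterministic predictions; no
  between-imputation variance (Rubin pooling) is produced.
* The tail rule (linear extension of the last segment) makes far-future
  medians sensitive to the final grid spacing; medians far beyond the
  follow-up horizon should be read as qualitative.
* Adapter slots (RSF, GBCM, CW-GBCM, DeepHit, DSM) are contracts, not
  implementations; grid results for them are skip records unless an
  adapter is registered.
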