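# Methods

This package implements and validates an impactability-evaluation
pipeline for outpatient case management programs in a Medicare-ACO-style
population: who was enrolled, who would have been comparable, how much
enrollment changed unplanned hospital events, event-days and payments,
and for whom the change was largest. Because the data such an evaluation
runs on (linked EHR + claims) are never public, the package ships a
synthetic-cohort generator with analytically known effects; every stage
is tested against that ground truth.

## Study design being emulated

Each **case** is a patient anchored at an enrollment month; each
potential **comparison** patient contributes up to a few candidate
episodes anchored at constructed match dates. An episode spans months
-12..-1 (complete baseline year, an eligibility requirement) and months
1..12 of follow-up, censored by death or loss of data; month 0 does not
exist. Outcomes per patient-month: an any-unplanned-event indicator, a
count of event-days (0..31), and a non-negative payment with excess
zeros.

## Synthetic cohort generator (`cohort`)

Structure, with defaults chosen to resemble a high-need ACO population:

- **Covariates.** A sparse binary block (default 500 indicators,
  prevalences drawn once per configuration from U(0.05, 0.90)),
  continuous covariates with MCAR missingness (default 10%), and an HCC
  comorbidity score ~ Gamma(2, 1.25).
- **Confounded enrollment.** Logistic treatment model on a designated
  subset of the binary covariates (default five confounders with
  log-odds 1.0 each); the intercept is calibrated numerically so the
  marginal enrollment probability equals `enrollment_rate` (default 5%).
- **Events.** Monthly any-event indicator with a logit linear in a
  calendar trend (default +0.01/month), the confounders, and — for
  enrolled patients in follow-up months — a level change
  `effect_level - benefit_event_scale * b(x)` (defaults -0.35 and
  0.0005/$). Baseline monthly event probability defaults to 0.15,
  matching roughly 2 ED visits + 1 admission per baseline year.
- **Event-days.** `any_event * (1 + Poisson(2))`, truncated at 31. This
  guarantees the binary/count consistency the outcome models assume; it
  is a *shifted* Poisson, so the zero-inflated Poisson analysis model is
  a deliberate approximation for this outcome (as it is for real data).
- **Payments.** Zero with probability `zip_zero_prob` (default 0.35),
  else Gamma with shape 1.5 and a log-linear mean in the confounders
  around $3,800/month (≈ $29k/patient-year including zeros, the scale of
  a high-need Medicare population). The pre-period payment mean is flat
  in time; the trend terms of the analysis model are exercised by the
  event process and fitted (correctly) near zero for payments.
- **Heterogeneous benefit.** `b(x) = benefit_intercept +
  benefit_coefficients . x` dollars/month of expected payment reduction
  under enrollment (defaults $100 + {400, 250, -150} on the first three
  covariates, i.e. $1,200-$9,600/patient-year — the scale at which the
  $1,200 operational screen is meaningful). Implemented by shifting the
  gamma-component mean, floored at $25; where the floor binds the
  realized reduction is smaller and the ground truth accounts for it.
- **Censoring.** Geometric on follow-up months only (hazard default
  0.03/month); death is absorbing censoring, with no competing-risk
  structure claimed.

**Ground truth.** `true_effect_per_100` computes the per-100-patient
1-year reductions among the enrolled: conditional expectations given
covariates are exact, Monte Carlo enters only through covariate draws
weighted by the enrollment probability (200k draws by default; the MC SE
is reported). The estimand assumes 12 observed follow-up months,
matching the "100 patients enrolled for 1 year" prediction target.

What the generator does **not** emulate: calendar-time effects, real
ICD/CPT code streams, correlation between event and payment processes
within a month, outcome dependence between candidate episodes of one
comparison patient, and informative censoring. Passing tests therefore
demonstrate correctness of the estimation machinery under the assumed
structure, not robustness to violations of it.

## Covariate preparation (`covariates`)

Continuous covariates get simple mean imputation within full-cohort HCC
deciles (empty deciles fall back to the overall mean with a warning),
then become high/low indicators split at the case median — values
exactly at the median are "low" (deterministic tie rule). Categorical
covariates get an explicit `missing` level. Indicators are screened on
case prevalence in [5%, 95%], then pairs with |Pearson r| > 0.8 are
pruned greedily in catalog order (the later-ordered member drops); both
rules record exclusion reasons. Greedy order-based pruning was chosen
over clustering because it is deterministic and order-stable.

## Propensity construction (`hdps`)

Covariates are ranked by the magnitude of the confounding bias they
could induce, the Bross bias multiplier
`BM = [pc1 (RR-1) + 1] / [pc0 (RR-1) + 1]`, with `pc1`/`pc0` the
prevalence among cases/comparisons and `RR` the covariate-outcome
relative risk, all from 0.5-continuity-corrected 2x2 counts. The
outcome anchoring the ranking is "any unplanned event during the
baseline year" — a pre-enrollment quantity, so the ranking never
conditions on post-treatment information — and RR is estimated among
comparison patients for the same reason. Covariates failing a two-sided
chi-square test of the covariate-outcome association at alpha = 0.05
drop out ("95% significance" screen).

Selection fits an L1 logistic path on standardized covariates over a
40-point geometric penalty grid anchored at the data-driven lambda_max;
each distinct active set is refit *unpenalized* and scored by
BIC = -2 loglik + k log n (relaxed-lasso style, giving BIC a
well-defined likelihood). The minimal-BIC active set wins, ties going
to the smaller set. The final propensity score is the plain ML logistic
fit on the selected set, clipped to [1e-6, 1-1e-6]; separation triggers
a weak (1e-6) ridge refit with a warning.

## Matching (`matching`)

Five rounds of exact matching on a nested, monotonically coarsening
schedule (default synthetic stand-ins: high-risk flag + confounder
indicators, dropping one variable per round). Within each round's
strata, cases still lacking matches receive comparisons by a globally
optimal variable-ratio assignment: every case gets 1..k_max (default 4)
comparisons as supply allows, no comparison episode — and no comparison
*patient* — is used twice, and the objective is lexicographic: maximize
the number of matches, then minimize total |propensity-score distance|.
This realizes "up to four of the *closest* eligible episodes" with a
well-defined global criterion; a tie-only bonus mode (`extra_bonus` as a
small float) is available, under which extra matches beyond the first
are taken only at (near-)zero distance.

Exactness and speed: the reference formulation is a min-cost flow
(networkx network simplex) over integer-scaled distances with a
lower-comparison-id tie-break. When supply is plentiful the problem
reduces exactly to a rectangular assignment (each case duplicated by its
slot count), solved by `scipy.optimize.linear_sum_assignment`; for large
instances the one-dimensional structure of |score| distances admits a
monotone (Monge) optimal assignment computed by an O(n m) dynamic
program. All three routes are cross-checked against each other and
against exhaustive enumeration in the tests. `max_candidates` optionally
prunes each case's candidate pool to its nearest comparisons before the
assignment (an eligibility window); the pipeline default is 60-80.

Balance is reported as absolute standardized mean differences,
`|m1 - m0| / sqrt((v1 + v0)/2)`, with the comparison side weighted by
(1/m) x ATT inverse-propensity weight; covariates with post-match SMD
above 0.25 form the residual-confounder adjustment set for the outcome
models. Residual imbalance on a few strong confounders is expected —
that is precisely why the flagged set feeds the regressions.

## Benefit score (`benefit`)

The benefit score is the estimated reduction in 12-month payments if a
patient enrolls — a treatment-effect prediction. Estimator: an
IPW-weighted linear model of the (censoring-rescaled) 12-month payment
total on baseline covariates, treatment, and treatment x covariate
interactions; the score is minus the fitted treatment contrast. The
linear-interaction form was chosen as the most transparent estimator of
the operative definition; the model object is a pluggable interface
(anything with `score(episodes)`) so richer effect-modeling estimators
can be substituted.

Categorization follows the program's operating rules exactly: positive
scores split at their own empirical quintile boundaries into 1..5,
negative scores into -5..-1 (higher = more benefit; exactly 0 counts as
non-positive); quintiles >= 2 are "high benefit", -5..1 "no/low
benefit"; scores above $1,200 carry the historic operational flag; risk
is "high" iff the 6-month risk probability strictly exceeds 13%.
Quintile boundaries are computed on the scoring population (cases) and
persisted, so new patients can be scored against frozen cut-points.

## Effect estimation (`effects`)

The analysis panel holds one row per matched episode per observed month,
intent-to-treat, with weight 1 for cases and
`(1/m) x ps/(1-ps)` (normalized to mean 1) for comparisons — ATT
weighting, matching the estimand "effect among the enrolled". Three
weighted segmented models per evaluation: logit/binomial (any event),
log/zero-inflated Poisson (event-days), log/zero-inflated gamma
(payments); terms: intercept, group, pre-slope t, group x t, post level,
group x post, post-slope (t-1)+, group x post-slope, plus the
balance-flagged adjustment covariates. Zero inflation is intercept-only
(structural zeros are not covariate-driven, for parsimony).

Fitting: logistic and Poisson by weighted IRLS; gamma (log link) by
iterated WLS with the shape by profile MLE (the mean score does not
involve the shape, so this is the joint MLE); ZIP by EM with a weighted
Poisson M-step, converging on relative log-likelihood change < 1e-8
within 500 iterations; the ZI-gamma likelihood factorizes exactly
(zeros only arise from the point mass), so pi is the weighted zero
fraction and the gamma part fits on the positives. statsmodels GLM is
the independent cross-check in the tests, never the fitting path for
the zero-inflated likelihoods.

**Per-100 transformation.** G-computation over enrolled cases: for each
case and month 1..12 the outcome mean is predicted as enrolled and under
the counterfactual comparison trajectory — the group x post and
group x post-slope terms zeroed, so cases keep their own pre-period
level and trend (difference-in-differences logic). Monthly differences
are summed, averaged over cases, scaled to 100 patients. Positive =
fewer events / dollars saved. The pre-trend interaction is retained in
the counterfactual by design; its sampling noise extrapolates into
follow-up and is the dominant variance component of the payment
estimate.

**Uncertainty.** Percentile 95% bootstrap (default 400 replications)
resampling whole matched sets (case + its comparisons), preserving the
clustered design; seeded and reproducible; more than 10% failed
replicates is an error. Stratified estimates fit risk strata separately
with the high-benefit indicator interacting with every group/period
term, predicting within stratum; strata under 10 cases are flagged
unstable. Harrell optimism correction: optimism is the mean over
resamples of [stratum effect of a resample-fit benefit model evaluated
on the resample] minus [the same model evaluated on the original
cohort]; corrected = apparent - optimism.

## Validation studies and their problem sizes

`impactability.studies` packages the simulation studies the test suite
asserts on; sizes were fixed once as study conditions:

- matching vs exhaustive enumeration: 100 random instances (<= 8 cases,
  <= 20 comparisons, k <= 3);
- balance: 50 confounded cohorts of 10,000 patients (5 confounders,
  log-odds 1.0, among 50 covariates, 5% enrollment);
- selection recovery: 50 cohorts of 5,000 patients, 5 confounders and 5
  instruments among 100 noise covariates; null-treatment selection on
  50 covariates;
- ZI MLE recovery at n = 10,000;
- per-100 payment recovery: 20 full-pipeline cohorts of 5,000 patients
  (~500 cases each), mean estimate within 3 combined MC SEs of truth —
  cohort count rather than single-cohort size carries the power here;
- CI calibration: 100 null cohorts of 1,500 patients, B = 200;
- benefit stratification: 50 cohorts of 5,000 patients with a planted
  continuous modification of $1,200/750/-450 per month on three
  covariates — sized, as a power calculation, so the stratum ordering is
  detectable per cohort at ~500 cases (point estimates); 3 null cohorts
  with B = 100 for the SE comparison;
- optimism: n = 300, B = 200, against an independent 5,000-patient fit.

## Numerical choices and degenerate inputs

Distances are rounded at 1e-9 resolution for integer flow costs; ties
break toward the lower comparison id. Propensity scores are clipped to
[1e-6, 1-1e-6]. SMD with two zero variances is 0 for equal means and
+inf otherwise. All-zero outcomes raise a degenerate-fit error; an
empty lasso selection yields the intercept-only propensity (scores =
treated fraction). Identical config + seed reproduces every output
byte-for-byte (wall-clock timings aside).

## Known limitations

The benefit estimator is linear-in-interactions; strongly nonlinear
effect modification would be attenuated (mitigated by the pluggable
interface). The ZIP model for event-days is misspecified relative to
the generator's shifted-Poisson days process, so day-level per-100
estimates are approximations (no ground-truth check is claimed for
them). The payment estimate has heavy-tailed sampling noise at a few
hundred cases (CV of roughly 40-50%), dominated by pre-trend
extrapolation — a property of the segmented specification, visible in
the wide bootstrap CIs, exactly as in the study design being emulated.
`max_candidates` pool pruning is an eligibility heuristic; with the
default windows no suboptimality has been observed against exact runs,
but optimality is only guaranteed for the unpruned solvers.
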