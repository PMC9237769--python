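# impactability

Evaluation pipeline for **impactability modeling** in outpatient case
management: does enrolling a high-need Medicare ACO patient into a case
management program reduce their unplanned hospital events, event-days
and payments — and can a dollar-valued **benefit score** identify, in
advance, the patients for whom it does?

Risk scores predict who will do badly; a benefit (impactability) score
predicts who will *improve if enrolled*. This package implements the
full evaluation chain such a score needs, for analysts studying
program-evaluation methodology on matched longitudinal cohorts:

1. **Synthetic cohorts** (`impactability.cohort`) — patient-episodes
   with a high-dimensional sparse covariate block, confounded
   enrollment, monthly outcomes over months -12..-1 and 1..12 with
   pre-trends and zero inflation, heterogeneous dollar-valued treatment
   benefit b(x), censoring — and the analytically known per-100-patient
   effects the analysis should recover.
2. **Covariate preparation** (`covariates`) — HCC-decile mean
   imputation, case-median high/low binarization, explicit missing
   categories, prevalence (5-95%) and correlation (|r| <= 0.8) screens.
3. **High-dimensional propensity score** (`hdps`) — covariates ranked by
   the Bross confounding-bias multiplier
   BM = [p_c1(RR-1)+1]/[p_c0(RR-1)+1] with a 95% significance screen,
   selected by L1 logistic regression tuned on the Schwarz criterion
   (BIC) of unpenalized refits, then a plain ML logistic propensity.
4. **Matching** (`matching`) — 5 nested rounds of exact matching, and
   within strata a *globally optimal* variable-ratio assignment (each
   case to 1..4 comparison episodes, min total |propensity distance|,
   via min-cost flow / assignment solvers), with SMD balance reporting
   and a >25% flag set for residual-confounder adjustment.
5. **Benefit score** (`benefit`) — IPW treatment-interaction payment
   model; score = estimated 12-month payment reduction if enrolled;
   signed quintiles (-5..-1, 1..5) with quintiles >= 2 labeled high
   benefit, the >$1,200 operational flag, and >13% high-risk
   categorization.
6. **Effects** (`effects`) — weighted segmented (interrupted
   time-series) GLMs on the patient-month panel — logit/binomial for
   any-event, log/zero-inflated Poisson for event-days,
   log/zero-inflated gamma for payments, with ATT x 1/m weights —
   transformed by g-computation into per-100-patient 1-year reductions
   with clustered bootstrap 95% CIs, benefit/risk-stratified estimates
   and Harrell optimism correction.

Model sketch for one outcome y in patient-month t (no month 0), group
g (case = 1), post = 1{t >= 1}:

    link E[y] = b0 + b1 g + b2 t + b3 g t + b4 post + b5 g post
                + b6 (t-1)+ + b7 g (t-1)+ + theta' z

The per-100 reduction is 100 x the mean over enrolled cases of
sum_{t=1..12} [E(y | counterfactual: b5 = b7 = 0) - E(y | factual)].

## Worked example

The numbered drivers under `analysis/` run the whole evaluation on a
5,000-patient synthetic cohort (about 500 enrolled cases, seed 2026)
and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_screen_covariates.py
python analysis/03_propensity_match.py
python analysis/04_benefit_scores.py
python analysis/05_effect_estimates.py   # ~2 min (bootstrap CIs, B=200)
python analysis/06_validation_studies.py
```

Abridged output (stages 01 and 03):

```
cohort: 5000 patients, 7265 episodes (522 case enrollments, 6743 candidate comparison episodes)
generator truth per 100 enrolled patients over 1 year:
  payment reduction  $556,263 (MC SE $634)
  event-months avoided  101.2 (MC SE 0.12)
prioritized 5 significant covariates; lasso-BIC selected 4: ['x1', 'x2', 'x0', 'x3']
matched 522 cases to 2088 comparison episodes (mean ratio 4.00, 0 unmatched)
balance: mean SMD 0.055 before -> 0.050 after matching
covariates above the 0.25 flag threshold (adjusted in outcome models): ['x1']
```

The bias-ranking screen keeps essentially only the planted confounders,
lasso-BIC selects four of the five, matching balances them, and the one
covariate still above the 25% SMD flag enters the outcome regressions.
Stage 05 then prints the evaluation table:

```
per-100-patient 1-year reductions (positive = fewer events / dollars saved):
  unplanned_events  overall                    95 [35 to 166]
  unplanned_events  high_benefit               98 [29 to 173]
  unplanned_events  no_low_benefit             89 [-10 to 213]
  payments          overall               487,211 [83,799 to 989,039]
  payments          high_benefit          890,984 [334,407 to 1,543,388]
  payments          no_low_benefit       -595,711 [-1,270,804 to 167,028]

generator truth (all enrolled): payments $556,263, event-months 101
```

The overall estimates bracket the generator truth (95 vs 101
event-months; $487k vs $556k), and the benefit score does what it is
for: the high-benefit stratum carries the large payment reduction
($891k per 100 patients, CI excluding zero) while the no/low-benefit
stratum shows none — the planted effect modification, recovered. Stage
04 additionally checks that the mean *true* 12-month benefit rises
across the estimated score quintiles, and stage 06 writes a one-table
summary of all validation studies (`results/validation_summary.csv`).
All numbers are reproducible bit-for-bit from the seed.

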