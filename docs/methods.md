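# Methods

## Estimand and identification

For a daily-resolution hospitalized cohort followed for τ = 28 days, let
L_t be covariates (baseline vector L_0 plus time-varying severity, hypoxia,
measurement indicators), A_t the daily corticosteroid exposure, C_t
discharge (loss to follow-up) at the end of day t, and Y death by end of
day t. Death is adjudicated before discharge within a day; both are
absorbing. Two regimes are compared: the dynamic rule d — treat on days
t* … t*+5, where t* is the first day the severe-hypoxia criteria are met —
and the static "never treat" rule. The estimand is the difference in 28-day
counterfactual mortality under each regime *combined with an intervention
preventing loss to follow-up*:

θ = P(Y^(d, C̄=0) = 1) − P(Y^(never, C̄=0) = 1).

Identification is by the longitudinal g-computation formula under
sequential conditional randomization: on every day, treatment and discharge
are independent of future counterfactuals given the recorded history. The
synthetic generator satisfies this by construction — everything that
influences treatment, death, or discharge is written into the person-day
table — so estimator error measured against the generator's truth is pure
estimation error, never hidden confounding.

## The synthetic cohort process

A latent severity score S_t drives the system:

- **Baseline** L_0: standardized age ~ N(0,1), sex ~ Bernoulli(0.5),
  a major-comorbidity flag ~ Bernoulli(0.3).
- **Severity**: S_0 = 0.1 + 0.45·age + 0.5·comorbid + 0.9·ε, then
  S_{t+1} = 0.06 + 0.85·S_t + 0.08·age + 0.10·comorbid
  + 0.6·β·A_t + 0.55·ε_t, with ε ~ N(0,1) and β the treatment effect
  (below). Severe hypoxia is S_t > 1.25.
- **Treatment propensity** (observational):
  logit P(A_t=1) = −5.0 + 0.2·S_t + 2.6·hypoxia_t + 0.1·age
  + 7.0·A_{t−1} − 5.0·1{cumulative treated days ≥ 6}.
  This encodes indication-driven prescribing: ≈11% of hypoxic person-days
  start a course, a started course continues with probability ≈0.9 per day,
  and courses wind down after about six days. All assignment probabilities
  stay well inside (0, 1) in every realizable history stratum — the
  positivity the g-formula needs. Treatment uptake (≈27% of patients) is
  somewhat higher than in the motivating EHR cohort; this is a deliberate
  design choice so that regime-adherent trajectories carry usable effective
  sample size.
- **Death hazard**: logit = −5.7 + 1.15·S_t + 0.3·age + 0.3·comorbid
  + β·1{treated within the last 6 days}.
- **Discharge hazard** (only if the day is survived):
  logit = −2.5 − 1.0·S_t — sicker patients stay, producing informative
  censoring.
- **Measurement**: a "labs charted today" indicator with
  logit = −0.4 + 0.8·S_t, carried as a covariate.

**The sharp null is a design invariant.** The treatment effect β (default
−0.3 log-odds) multiplies *both* treatment pathways: the direct shift on
the death hazard and the severity response (0.6·β). Setting β = 0 therefore
makes every counterfactual risk identical under any regime — exactly, not
just in expectation — which the test suite exploits. Any β ≠ 0 produces
treatment-confounder feedback (treatment lowers severity; severity drives
future treatment, death and discharge).

Coefficients were calibrated once, at design time, to a realistic acute
respiratory cohort on the scale of the motivating study: ≈50% of patients
ever hypoxic, ≈27% ever treated, ≈17% observed 28-day mortality with ≈73%
discharged before day 28, counterfactual risks ≈32% (never treat) and ≈26%
(dynamic regime), risk difference ≈ −7 percentage points. They are not
revisited per experiment.

Randomness is counter-based: each draw is a hash of (seed, patient, day,
channel), so cohorts are bit-reproducible, growing `n_patients` appends
patients without perturbing existing ones, and forcing a regime leaves the
untouched channels (severity noise, death, discharge) identical — which is
why the β = 0 null holds draw for draw.

### The discrete replica and the population-cohort oracle

A finite-state copy of the process (binary severity = hypoxia, no baseline
covariates, all hazards logistic, horizon 3) admits exact counterfactual
risks by summing over trajectories (`enumerate_truth`). Its observational
law can also be *enumerated*: every trajectory becomes a pseudo-patient
weighted by its exact probability. On this weighted "population cohort",
empirical conditional means equal true ones, so saturated-model estimators
must reproduce the enumeration to numerical precision. This is the
strongest correctness check in the package: g-computation, IPW with true
propensities and SDR all agree with the oracle to ≤1e−6 (observed: ~1e−16).
It is the reason all estimators support per-patient frequency weights.

## Estimators

All three routes share a patient-by-day panel with history-derived
features: previous-day treatment, any treatment in the last 5 days,
course-completed flag, hypoxia-seen flag — the same summaries the generator
uses, so the treatment, censoring and hazard models are correctly
specifiable by a logistic in these features.

- **Per-day nuisance fits.** The treatment mechanism P(A_t=1 | H_t) and the
  censoring mechanism P(C_t=0 | survived, H_t, A_t) are fit day by day,
  cross-fit over patient-level folds (default 10; the replicated studies
  use 5). Cells with fewer than 12 rows or a constant target fall back to
  the weighted mean. Fitted probabilities are trimmed to [0.01, 0.99]
  (censoring: [0.01, 1]).
- **Stage regressions.** Each backward stage fits the discrete-time death
  hazard h_t (log loss; fully observed) and the continuation value q_t
  (squared loss, among survivors who remained uncensored) and composes
  m_t = h_t + (1 − h_t)·q_t. The decomposition matters: because death
  precedes discharge within a day, a single pooled regression that drops
  censored rows conditions on an event *downstream* of death and is
  selection-biased (an error of ≈2e−2 on the oracle; the decomposition is
  exact).
- **SDR.** The stage-t regression target is the doubly robust pseudo-outcome
  φ_{t+1}; after fitting, φ_t = r_t(target − m_t(A_t)) + m_t(d_t) with
  r_t = 1{A_t = d_t}·1{kept} / (g^A_t·g^C_t). The point estimate is the
  mean of φ_0; SE = sd(φ_0)/√n; 95% CIs are normal-approximation. The
  per-patient φ_0 − ψ̂ values are the EIF contributions and feed the
  contrast variance (risk difference, risk ratio, odds ratio via the delta
  method on the log scale).
- **Weight control.** Over 28 days the cumulative adherence/censoring
  products are heavy-tailed (staying hospitalized 28 days while healthy is
  itself rare). The running products are capped day by day at their 0.999
  quantile (configurable), and the per-stage ratios used in the recursion
  are derived from the capped products so the recursion and the weights
  agree. A result gains a warning when >5% of at-risk person-days sit at
  the propensity trimming bound.
- **g-computation** reports the mean stage-0 regression under the regime;
  its SE uses the one-step EIF assembled around the ICE fits (it needs the
  fitted propensities, which `fit_nuisances` always produces). **IPW** is
  the Horvitz–Thompson mean with the capped weights; its SE is the sample
  variance of the weighted score.
- **Super learner.** Nuisance regressions accept a candidate library
  (intercept-only, linear/logistic, gradient-boosted trees, k-NN, and a
  saturated stratum-mean learner for discrete covariates). With ≥2
  candidates, V-fold CV predictions are stacked with convex weights
  minimizing CV loss (SLSQP on the simplex; falls back to the best single
  candidate, and never does worse than it in CV). The replicated studies
  use the linear/logistic candidate alone — correctly specified for this
  generator and an order of magnitude faster; the ensemble is exercised in
  its own tests.

## Model-first designs

Designs A–I condition on reaching hypoxia (time zero = first hypoxic day)
and fit lifelines Cox models with Efron ties (daily binning ⇒ heavy ties;
`ties="breslow"` dispatches to statsmodels PHReg). Exposure windows: "up to
k days after hypoxia" includes the hypoxia day and the next k calendar
days; pre-hypoxia treatment counts as exposed unless the design excludes
pre-treated patients. Design E/I censor at post-window treatment initiation
(treatment during a day precedes that day's death adjudication, so the
censoring wins same-day ties); the "1-day" phrasing sometimes attached to
the 5-day censoring design is treated as a typo — censoring applies after
the 5-day window. Design J is the counting-process time-varying model from
admission with current-day exposure (an ever-exposed coding is available
behind a flag). Covariates: baseline variables plus time-zero severity
(A–I) or current-day severity and hypoxia (J). Exclusions are logged per
reason and patients-in always equals analyzed + excluded.

## Standard study sizes

The replicated experiments (used by the test suite and the acceptance
script) run at sizes chosen to give stable summaries in a few minutes on
one core: parameter recovery — 50 replicates of n = 5000 with the truth
fixed by a 500,000-draw forced-regime Monte Carlo; double robustness — 50
replicates of n = 4000 on the discrete replica (its enumerated truth is
exact and its 3-day horizon keeps adherence weights bounded, isolating
estimator properties from long-horizon positivity pathology); null-effect
design study — 50 replicates of n = 2000 fitting designs A, B, F.

## Limitations

- The generator emulates the *structure* of an EHR cohort (feedback,
  informative discharge, indication-driven prescribing), not its content:
  no real covariate distributions, no competing discharge destinations, no
  drug-level heterogeneity, and the measurement indicator modulates only
  the covariate set, not true missingness. Passing tests demonstrate
  estimator correctness under the stated assumptions; they cannot rule out
  unmeasured confounding in real data.
- With a 28-day horizon and modest uptake, the dynamic-regime effective
  sample size is small; single-cohort SDR intervals are wide and
  occasionally a replicate's weight tail dominates (the EIF SE reflects
  this honestly). Aggregation across replicates, not any single run, is
  the supported evidence.
- Normal-approximation CIs can be anti-conservative in the extreme weight
  tail; no bootstrap alternative is provided.
- No TMLE variant is implemented; SDR plus the singly robust comparators
  cover the intended methodological contrast.
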