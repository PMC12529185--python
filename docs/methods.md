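# Methods

This note documents the statistical machinery in `ttemul`: the estimands
and estimators, the synthetic data-generating world and its oracle, the
numerical conventions, and the design choices made where several
reasonable conventions exist.

## Estimands and follow-up conventions

Time is measured in integer days from a scenario-wide origin; analysis
proceeds on a 30-day interval grid (interval k covers follow-up days
`[30k, 30(k+1))` from the index date). For a static regime a = (class,
sustained?) the target is the counterfactual cumulative incidence
`F_a(k)` of the composite outcome (nonfatal MI, nonfatal stroke,
cardiovascular death — the composite is configurable) by the end of
interval k, in a hypothetical world where everyone initiates class a (and,
for per-protocol regimes, sustains coverage without initiating a
comparator) and right-censoring is abolished. Non-cardiovascular and
unknown-cause deaths are treated as censoring events: the estimand is a
cause-specific risk, not a subdistribution (competing-risk) risk. This is a
documented limitation: `F_a` answers "risk if censoring, including death
from other causes, were removed", not "risk in the presence of competing
death".

Follow-up ends at the earliest of: outcome, death censoring,
disenrollment, administrative end of data, the protocol horizon (default
30 intervals ≈ 2.5 years), and in PP mode artificial censoring at the
protocol deviation. Within-interval ties among the real causes are
resolved by the fixed precedence outcome > death > disenrollment >
administrative end. Artificial PP censoring is the one cause resolved at
*day* level against the others: its day is known exactly from coverage
arithmetic and always falls at or before any same-interval event or censor
day, so the deviating interval contributes no at-risk person-time — except
that an outcome strictly before the deviation day still counts (the
patient was on protocol when it occurred). Without the day-level rule,
events occurring after a same-interval deviation would leak into the PP
risk sets and bias hazards upward by roughly (deviation rate × hazard) per
interval.

Administrative censoring is marked on a row only when the data end
mid-interval; a patient observed through the full horizon simply has no
terminal mark (their last interval is complete and remains at risk), and
is tallied under "administrative end" in the attrition report.

## Exposure from dispensings

Each dispensing covers the half-open window starting on the dispense day
and lasting twice the days' supply; the doubled window absorbs imperfect
adherence. Coverage windows are unioned (an early refill never shortens
coverage, and no stockpiling credit extends a fill beyond its own doubled
window), and a gap of at most 90 days between the running coverage end and
the next dispensing of the same medication counts as exposed.
Discontinuation is the end of the first merged exposure episode; crossover
is the first covered day of a comparator after the index day; a same-day
tie is classified as crossover. The union reading resolves a pathology of
a strictly literal "closest prior dispensing" rule, under which a short
fill nested inside a longer fill's coverage would mark covered days
unexposed.

## Person-interval dataset and missingness

Covariates are encoded with the missingness-indicator approach: per
covariate and interval, an indicator `M_k` of measurement in that interval
(latest measurement within an interval wins — verified against a per-day
scan), and an imputed value `L_k` = last observed value at or before k,
falling back to the cohort baseline imputation (mode of observed baselines
for categorical covariates, mean for continuous). Measurements up to a
configurable window before the index (default 365 days) contribute to the
baseline value but not to the interval-0 indicator. Both values and
indicators enter every adjustment model. A covariate with no observed
baseline anywhere in the cohort is an error — there is no imputation basis.

## Nuisance models

Propensity scores for treatment initiation (one binary model per arm on
baseline rows), treatment continuation (probability of a protocol
deviation, PP only) and each right-censoring cause are fitted at each time
point separately by a cross-validated stacking ensemble (super learner):
candidate learners (default library: intercept-only, main-terms logistic,
L1-penalized logistic with small-grid CV) are fitted on V folds (default
10; the pipeline default uses 5 for desk-scale data) and combined with
simplex weights minimizing the cross-validated Bernoulli log-loss
(SLSQP on the simplex); a degenerate convex fit falls back to the discrete
super learner (best single learner), and the ensemble is guaranteed never
to have worse CV loss than any single learner. A constant target returns a
flagged constant predictor rather than an error, since a censoring cause
can be absent at desk scale.

Two conventions matter for correctness and are deliberate:

* **Sequential conditioning.** Within an interval, causes claim rows in
  the order deviation → deaths → disenrollment; each cause's model is
  fitted among rows not claimed by an earlier cause. The product of fitted
  complements is then exactly the probability of remaining at risk, and
  main-terms logistic models are exactly correct in the bundled
  validation worlds.
* **Bounding.** The floor (default 0.005) applies to the quantities that
  enter weight denominators: initiation propensities directly (bounded to
  [0.005, 0.995]) and the remain-uncensored factor `1 − p̂` for cause
  models (so cause probabilities are capped at 0.995 but *not* floored
  upward, and an absent cause contributes a factor of exactly 1). Flooring
  rare causes up at 0.005 would inflate cumulative weights by about 0.5%
  per interval per rare cause; the package's weight diagnostics test
  (weights average to the event-free survival probability per arm) caught
  exactly this.

Intervals with fewer than `min_events` (default 25) modelled events fall
back to a single fit pooled over time with the interval index as a
predictor.

Cumulative weights multiply the inverse initiation propensity with the
per-interval inverse probabilities of remaining uncensored (and
undeviated, for PP); censored and non-adherent rows get weight 0.
Truncation styles: none, percentile of the positive-weight distribution
(default 99th), absolute cap (defaults 20 for IPW, 200 for the TMLE
targeting weights), applied to the final cumulative weight.

## Estimators

**Weighted product-limit.** Interval hazard = weighted event fraction
among at-risk rows of the arm; `F(k) = 1 − Π(1 − λ̂_j)`. SEs by the
delta-method influence-curve expansion over interval hazards, treating
weights as known — the conservative convention. With unit weights this
reduces exactly to one minus Kaplan-Meier survival (cross-checked against
`lifelines` in the tests). If an at-risk interval has zero total weight
while later data exist, the curve is truncated there and flagged.

**Longitudinal TMLE.** Sequential regression (iterated conditional
expectation), run separately per reported horizon k\*: initialize with the
event-by-k\* indicator; for j = k\*−1 down to 0, regress the iterated
outcome on current covariates among the regime's at-risk, uncensored,
adherent rows (fractional outcomes handled by the two-row expansion so
penalized logistic learners apply unchanged; outcome-regression methods:
`lasso` (default), `glm`, `intercept`, `saturated` stratum means of the
current row, `saturated_history` stratum means of the full covariate
history), predict for everyone still at risk under the regime, then
fluctuate with an intercept-only weighted logistic update whose weight is
the capped cumulative inverse-probability product through j. The clever
covariate enters as a *weight*, not a regressor — more stable under heavy
weights. The fluctuation equation is solved by bracketed root-finding
(`brentq`, tolerance 1e-13) on [−15, 15]; a degenerate fluctuation falls
back to the untargeted fit with a warning and a flag, never silently.
`F̂(k\*)` is the mean targeted baseline prediction over the whole cohort;
the influence curve is the standard sequential-regression sum plus the
plug-in residual, and the targeting step makes its empirical mean zero to
solver precision (the tests require |mean(IC)| ≤ 1e-6·sd(IC) at every
horizon). Monotonicity across horizons is enforced by isotonic projection
and flagged when it binds. A Markov data-generating world makes
`saturated` (current-row strata) exactly correct; `saturated_history` is
exact without any Markov assumption and underlies the saturated-instance
equivalence checks (TMLE = saturated-IPW = exact g-computation to 1e-8).

**Exact g-computation.** `gcomp_enumerate` sums event probabilities over
all covariate histories of a finite-support discrete law (guard:
≤ 100 000 histories); `empirical_discrete_law` builds that law from a
small long dataset by empirical frequencies conditioned on the full
history. Together they provide the small-instance oracle.

**Inference.** `se = sd(IC)/√n` (population sd — the IC is centered by
construction), Wald CIs, two-sided normal p-values. Both arms are
estimated on one cohort, so contrast SEs difference the per-patient
influence curves rather than assuming independence.

## Contrasts and sensitivity analyses

RD at the horizon; ARD = time-average of per-interval risk differences
(the area between step curves divided by follow-up length — dimensionless,
on the risk scale; this convention is chosen over risk×time units so ARD
and RD are directly comparable); NNT = 1/|RD| rounded to the nearest
integer, reported only when the RD CI excludes 0. The secondary IPW hazard
ratio comes from weighted pooled logistic regression of the event
indicator on a treated-arm indicator and an interval main effect, with a
patient-clustered sandwich variance; proportionality is not assumed and
the HR is reported for comparability only. The effect-modification test is
a Wald z-test that PP RDs are equal between two disjoint subgroups;
subgroup analyses re-run the entire estimation chain, including refitting
every propensity model, within the subgroup.

The g-value is the smallest additive bias on the RD scale that, applied
toward the null, makes the 95% CI include 0: `max(0, |RD| − 1.96·se)`,
also reported as a fraction of the estimate. This additive-shift
definition is a transparent stand-in for richer unmeasured-confounding
formulations; the module exposes the bias-shift machinery so an
alternative definition can be slotted in. Truncation sweeps re-estimate
contrasts under each truncation spec without refitting nuisance models.

## The synthetic EHR world

`ScenarioConfig` specifies a complete generative model, all logistic or
linear with named coefficients: baseline covariates; softmax treatment
initiation over per-class linear scores (confounded); first-order-Markov
time-varying covariates driven by the previous value and current exposure;
per-interval discontinuation and crossover; per-cause censoring
(disenrollment, non-cardiovascular death, with a configurable fraction of
deaths relabelled unknown-cause); a discrete-time event hazard; and the
dispensing process (days'-supply and refill-delay distributions). Two
structural choices make the world coherent with the analysis:

* the causal exposure *is* the dispensing-derived coverage state — the
  hazard and covariate dynamics read coverage (with gap bridging) at
  interval starts, so the exposure engine recovers exactly the exposure
  that drives outcomes; and
* within an interval the canonical longitudinal ordering L → C → Y holds:
  censoring and deviation are decided before the interval's event draw, so
  the event probability among uncensored at-risk patients equals the
  structural hazard. (The opposite ordering makes uncensored rows
  event-enriched and biases every estimator upward — found and fixed by
  validating against the oracle.)

Ground truth is Monte-Carlo g-computation: the same simulator re-run with
censoring off and treatment forced (sustained regimes force unbroken
coverage; initiation-only regimes keep natural persistence dynamics),
reporting empirical counterfactual risks with binomial MC SEs.

Bundled scenarios: `default_scenario` (realistic flavour: four covariates
including a continuous HbA1c with treatment-responsive dynamics, 10%
measurement missingness, mixed 30/60/90-day supplies with random refill
delays, 2% same-day dual-class initiations to exercise attrition);
`confounded_scenario` (strong baseline + time-varying binary confounding
of initiation, persistence and disenrollment, no missingness, clean
15-day supplies refilled every 30 days so coverage ends exactly on
interval boundaries and main-terms logistic nuisance models are exactly
correct); `randomized_scenario`, `null_scenario`, `four_arm_scenario`.
The generator does not model realistic disease progression, site
heterogeneity, coded diagnoses, dose or agent switching within class, or
pre-index dispensing histories (new-user washout arithmetic is pinned by
hand-built fixtures instead; the generator exercises attrition through
dual-class initiations). Passing tests therefore demonstrate correctness
of the *algorithms* under the stated causal structure, not robustness to
every feature of real claims data.

## Problem sizes and validation design

Validation studies are sized for a single CPU: the randomization limit
uses n = 2000 patients over K = 10 intervals against an oracle of 150 000
Monte-Carlo draws; double-robustness uses 20 replicates of n = 4000 (each
replicate's dataset shared across the four nuisance configurations) plus
60 replicates of n = 500, with bias assessed against a 300 000-draw
oracle; CI coverage uses 100 replicates of n = 1000; the
effect-modification type-I-error study uses 400 replicates of n = 300.
Comparisons against the Monte-Carlo oracle use three times the combined
standard error (estimator influence-curve SE and oracle MC SE in
quadrature), since at these sample sizes the estimator's own sampling
error dominates any affordable oracle error.

## Known limitations

* Cause-specific (not subdistribution) risks; no competing-risk estimand.
* Static regimes only; no dynamic, covariate-responsive strategies.
* The per-horizon sequential-regression TMLE refits the full recursion per
  horizon (O(K²) regressions for a full curve); pooled-over-time variants
  are not implemented.
* Product-limit SEs treat weights as fixed (conservative); no cross-fitted
  nuisance estimation.
* The HR is a convenience summary; it inherits all the usual
  non-collapsibility and proportionality caveats.
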