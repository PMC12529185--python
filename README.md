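# ttemul — target-trial emulation of sustained medication exposure

`ttemul` implements the analysis pipeline used to emulate head-to-head
randomized trials of glucose-lowering medication classes from
pharmacy-dispensing and EHR-style data, and estimate their comparative
effect on major adverse cardiovascular events (MACE): from raw dispensing
records all the way to counterfactual cumulative incidence curves, risk
differences and sensitivity analyses. It is aimed at pharmacoepidemiologists
and causal-inference methodologists who want a tested, inspectable
implementation of the longitudinal targeted-learning workflow on data they
can fully control.

Because real multi-site EHR extracts are proprietary, the package ships a
first-class synthetic EHR generator with known causal structure — confounded
initiation, time-varying confounding of persistence, informative censoring,
and dispensing-level refill behaviour — plus a Monte-Carlo g-computation
oracle, so every pipeline stage is validated against ground truth.

## What it computes

**Design.** New-user, active-comparator cohorts: an index fill qualifies if
no compared class was dispensed in the prior washout (default 730 days);
ordered eligibility predicates produce an attrition flow with exact count
conservation. Follow-up proceeds in 30-day intervals until the earliest of
MACE, non-cardiovascular or unknown-cause death, disenrollment,
administrative end of data, or — in per-protocol (PP) analyses — artificial
censoring at the first treatment-protocol deviation. Intention-to-treat
(ITT) analyses ignore deviations.

**Exposure.** A dispensing covers `[t, t + 2·days_supply)`; gaps of at most
90 days between the running coverage end and the next fill count as exposed.
Discontinuation is the end of the first exposure episode; crossover is the
first covered day of a comparator class.

**Estimation.** Writing `A` for the initiated class, `L̄_k` for covariate
history (LOCF-imputed with missingness indicators `M_k`), and `λ_a(k)` for
the discrete-time cause-specific hazard, the package estimates the
counterfactual cumulative incidence
`F_a(k) = 1 − Π_{j≤k} (1 − λ_a(j))` per arm by

1. unadjusted product-limit (unit weights),
2. IPW product-limit under a nonparametric MSM, with cumulative weights
   `w_i(k) = 1{follows regime}/( g_A(L_0) · Π_{j≤k} Π_c (1 − Pr[C_j = c | L̄_j]) )`
   built from super-learner propensities for initiation, continuation and
   each censoring cause fitted at each time point separately, and
3. longitudinal TMLE by sequential regression (iterated conditional
   expectation) with L1-penalized outcome regressions and an intercept-only
   weighted logistic fluctuation per step — doubly robust, with
   influence-curve SEs.

Contrasts: risk difference at the horizon, average risk difference (area
between curves per unit follow-up), NNT = 1/RD (suppressed when the CI
crosses 0), a secondary IPW hazard ratio, subgroup re-fits with a Wald
effect-modification test, weight-truncation sweeps (99th percentile;
absolute caps 20 for IPW, 200 for TMLE) and g-values (the additive bias
needed to nullify a conclusion).

## Worked example

```python
from ttemul import scenarios
from ttemul.pipeline import EmulationConfig, run_emulation

scenario = scenarios.confounded_scenario(n_patients=2000, seed=7)
config = EmulationConfig(scenario=scenario, seed=7, modes=("PP",),
                         q_method="glm")
report = run_emulation(config)

print(report.attrition.to_text())
for est in ("unadjusted", "ipw", "tmle"):
    c = report.contrasts[("PP", est)]
    print(f"{est:10s} RD = {c.rd:+.4f} "
          f"(95% CI {c.rd_ci[0]:+.4f} to {c.rd_ci[1]:+.4f}), "
          f"ARD = {c.ard:+.4f}, NNT = {c.nnt}")
```

prints

```
New-user index fills screened: 2000
Index fills entering cohort: 2000
  arm glp1ra: 1223
  arm su: 777
unadjusted RD = +0.0693 (95% CI +0.0202 to +0.1183), ARD = +0.0374, NNT = 14
ipw        RD = +0.1413 (95% CI +0.0799 to +0.2027), ARD = +0.0776, NNT = 7
tmle       RD = +0.1484 (95% CI +0.0925 to +0.2044), ARD = +0.0808, NNT = 7
```

This world assigns sicker patients preferentially to the protective GLP-1RA
arm, so the unadjusted sulfonylurea-vs-GLP-1RA risk difference (+0.069) is
badly attenuated; IPW and TMLE recover the Monte-Carlo ground truth
(`ground_truth(...)` gives an oracle RD of +0.146 for this configuration).
The positive RD means higher 6-interval (180-day) MACE risk under sustained
sulfonylurea use than under sustained GLP-1RA use; NNT = 7 is the number of
patients treated with the control class instead of the treated class to
avoid one event over that horizon.

A thin CLI mirrors the library: `ttemul simulate`, `ttemul estimate`,
`ttemul report`, `ttemul sensitivity` (see `--help`).

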