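"""Bundled data-generating scenarios.

Each preset returns a :class:`~ttemul.config.ScenarioConfig` describing a
complete synthetic world.  Coefficients are on the log-odds scale per 30-day
interval.  The presets serve distinct purposes:

``default_scenario``
    The workhorse 2-arm world (sulfonylurea vs GLP-1 receptor agonist):
    confounded initiation, a continuous and several binary covariates,
    time-varying confounding of continuation and censoring, 10% covariate
    missingness, mixed 30/60/90-day supplies with random refill delays, and
    a small rate of same-day dual-class initiation so cohort attrition is
    exercised end-to-end.

``confounded_scenario``
    A stripped-down strongly confounded world with one static and one
    time-varying binary confounder, clean 15-day supplies refilled every 15
    days (so dispensing-derived protocol deviations map one-to-one onto
    latent interval-level continuation decisions, making main-terms logistic
    propensity models exactly correct), no measurement missingness, and
    informative censoring.  Used for double-robustness and coverage studies.

``randomized_scenario``
    Treatment assigned independently of covariates and censoring independent
    of everything: the world where unadjusted, IPW and TMLE estimates must
    all agree with the oracle.

``null_scenario``
    As ``confounded_scenario`` but with zero treatment effect on the hazard.
"""

from __future__ import annotations

from .config import CovariateSpec, DispensingSpec, ScenarioConfig

TWO_ARM = ("su", "glp1ra")

#: 15-day fills refilled every 30 days: each fill's doubled coverage window
#: exactly abuts the next fill, so coverage ends on an interval boundary and
#: a latent stop at interval k yields a protocol deviation at day 30k with
#: exposure 0 from interval k on.
CLEAN_DISPENSING = DispensingSpec(
    supplies=(15,), supply_probs=(1.0,),
    refill_delay_min=15, refill_delay_max=15,
)


def default_scenario(
    n_patients: int = 4000, seed: int = 0, horizon_days: int = 900
) -> ScenarioConfig:
    return ScenarioConfig(
        n_patients=n_patients,
        med_classes=TWO_ARM,
        horizon_days=horizon_days,
        baseline_covariates=[
            CovariateSpec("age", "continuous", {"mean": 62.0, "sd": 10.0}),
            CovariateSpec("ascvd", "binary", {"p": 0.3}),
            CovariateSpec("hba1c", "continuous", {"mean": 8.3, "sd": 1.4}),
            CovariateSpec("smoker", "binary", {"p": 0.2}),
        ],
        covariate_dynamics={
            # HbA1c drifts toward its previous value, improves on treatment
            "hba1c": {
                "kind": "continuous",
                "intercept": 1.7,
                "prev": 0.8,
                "exposure": {"su": -0.15, "glp1ra": -0.3},
                "sd": 0.35,
            },
        },
        treatment_model={
            "su": {"intercept": 0.0},
            "glp1ra": {
                "intercept": -1.1,
                "ascvd": 1.0,
                "hba1c": 0.08,
                "age": -0.01,
            },
        },
        continuation_model={
            "discontinue": {"intercept": -2.9, "hba1c": 0.06},
            "crossover": {"intercept": -4.2, "hba1c": 0.1},
        },
        hazard_model={
            "intercept": -7.4,
            "age": 0.045,
            "ascvd": 1.1,
            "hba1c": 0.1,
            "smoker": 0.4,
            "exposure": {"su": 0.0, "glp1ra": -0.5},
        },
        censoring_model={
            "disenrollment": {"intercept": -4.4, "smoker": 0.3},
            "noncv_death": {"intercept": -8.6, "age": 0.05},
        },
        unknown_death_frac=0.05,
        missingness_rate=0.1,
        dual_initiation_rate=0.02,
        dispensing_spec=DispensingSpec(),
        seed=seed,
    )


def confounded_scenario(
    n_patients: int = 4000,
    seed: int = 0,
    horizon_days: int = 180,
    treatment_effect: float = -0.7,
) -> ScenarioConfig:
    """Strongly confounded, informatively censored 2-arm world (binary L)."""
    return ScenarioConfig(
        n_patients=n_patients,
        med_classes=TWO_ARM,
        horizon_days=horizon_days,
        baseline_covariates=[
            CovariateSpec("ascvd", "binary", {"p": 0.35}),
            CovariateSpec("poor_control", "binary", {"p": 0.5}),
        ],
        covariate_dynamics={
            "poor_control": {
                "kind": "binary",
                "intercept": -0.5,
                "prev": 1.7,
                "exposure": {"su": -0.2, "glp1ra": -0.9},
            },
        },
        treatment_model={
            "su": {"intercept": 0.0},
            "glp1ra": {"intercept": -0.4, "ascvd": 1.3, "poor_control": 0.9},
        },
        continuation_model={
            # single deviation channel keeps the logistic continuation
            # model exactly correct (no mixture of deviation causes)
            "discontinue": {"intercept": -2.3, "poor_control": 0.8},
            "crossover": {"intercept": -30.0},
        },
        hazard_model={
            "intercept": -3.9,
            "ascvd": 1.3,
            "poor_control": 0.9,
            "exposure": {"su": 0.0, "glp1ra": treatment_effect},
        },
        censoring_model={
            "disenrollment": {"intercept": -3.0, "poor_control": 0.8},
            "noncv_death": {"intercept": -30.0},
        },
        unknown_death_frac=0.0,
        missingness_rate=0.0,
        dispensing_spec=CLEAN_DISPENSING,
        seed=seed,
    )


def randomized_scenario(
    n_patients: int = 2000,
    seed: int = 0,
    horizon_days: int = 300,
    treatment_effect: float = -0.6,
) -> ScenarioConfig:
    """Randomized treatment, independent censoring, modest discontinuation."""
    return ScenarioConfig(
        n_patients=n_patients,
        med_classes=TWO_ARM,
        horizon_days=horizon_days,
        baseline_covariates=[
            CovariateSpec("ascvd", "binary", {"p": 0.4}),
            CovariateSpec("poor_control", "binary", {"p": 0.5}),
        ],
        covariate_dynamics={
            "poor_control": {"kind": "binary", "intercept": -0.3, "prev": 1.2},
        },
        treatment_model={
            "su": {"intercept": 0.0},
            "glp1ra": {"intercept": 0.0},
        },
        continuation_model={
            "discontinue": {"intercept": -2.6},
            "crossover": {"intercept": -30.0},
        },
        hazard_model={
            "intercept": -3.6,
            "ascvd": 0.9,
            "poor_control": 0.5,
            "exposure": {"su": 0.0, "glp1ra": treatment_effect},
        },
        censoring_model={
            "disenrollment": {"intercept": -3.3},
            "noncv_death": {"intercept": -5.0},
        },
        unknown_death_frac=0.05,
        missingness_rate=0.0,
        dispensing_spec=CLEAN_DISPENSING,
        seed=seed,
    )


def four_arm_scenario(
    n_patients: int = 8000, seed: int = 0, horizon_days: int = 180
) -> ScenarioConfig:
    """Randomized 4-arm world with a configured ordering of class effects
    (sulfonylurea least protective through GLP-1RA most protective)."""
    from .config import ALL_CLASSES

    return ScenarioConfig(
        n_patients=n_patients,
        med_classes=ALL_CLASSES,
        horizon_days=horizon_days,
        baseline_covariates=[
            CovariateSpec("ascvd", "binary", {"p": 0.35}),
        ],
        covariate_dynamics={},
        treatment_model={med: {"intercept": 0.0} for med in ALL_CLASSES},
        continuation_model={
            "discontinue": {"intercept": -2.8},
            "crossover": {"intercept": -30.0},
        },
        hazard_model={
            "intercept": -3.1,
            "ascvd": 0.8,
            "exposure": {
                "su": 0.0, "dpp4i": 0.15, "sglt2i": -0.35, "glp1ra": -0.7,
            },
        },
        censoring_model={
            "disenrollment": {"intercept": -3.5},
            "noncv_death": {"intercept": -30.0},
        },
        unknown_death_frac=0.0,
        missingness_rate=0.0,
        dispensing_spec=CLEAN_DISPENSING,
        seed=seed,
    )


def null_scenario(
    n_patients: int = 2000, seed: int = 0, horizon_days: int = 180
) -> ScenarioConfig:
    """Confounded world with no treatment effect on the hazard."""
    return confounded_scenario(
        n_patients=n_patients,
        seed=seed,
        horizon_days=horizon_days,
        treatment_effect=0.0,
    )
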