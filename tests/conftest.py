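import warnings

import numpy as np
import pandas as pd
import pytest

from ttemul import Regime, generate_population, ground_truth, scenarios
from ttemul.nuisance import LearnerLibrary
from ttemul.pipeline import EmulationConfig, run_emulation

warnings.filterwarnings("ignore", message="constant target")


@pytest.fixture(scope="session")
def fast_library():
    """Lean learner library used where super-learner machinery itself is
    not under test."""
    return LearnerLibrary(learners=("glm",), cv_folds=3, seed=0)


@pytest.fixture(scope="session")
def randomized_run(fast_library):
    """One full pipeline run on the randomized scenario plus its oracle."""
    cfg = scenarios.randomized_scenario(n_patients=2000, seed=17)
    ec = EmulationConfig(
        scenario=cfg, seed=17, q_method="glm", modes=("PP", "ITT"),
        library=fast_library,
    )
    report = run_emulation(ec)
    truth = ground_truth(
        cfg,
        [Regime("su", True), Regime("glp1ra", True)],
        n_mc=150_000,
    )
    return cfg, report, truth


@pytest.fixture(scope="session")
def confounded_tables():
    cfg = scenarios.confounded_scenario(n_patients=2500, seed=23)
    return cfg, generate_population(cfg)


@pytest.fixture(scope="session")
def confounded_run(fast_library):
    """A per-protocol IPW run on the strongly confounded world, whose
    cumulative weights are heavy-tailed (truncation caps bind)."""
    cfg = scenarios.confounded_scenario(n_patients=3000, seed=11)
    ec = EmulationConfig(
        scenario=cfg, seed=11, q_method="saturated", modes=("PP",),
        estimators=("ipw",), library=fast_library,
    )
    return cfg, run_emulation(ec)


def make_toy_long(rows):
    """Long-format frame from compact row tuples
    (pid, k, arm, A, adherent, censor, Y, covariates...)."""
    out = []
    for r in rows:
        pid, k, arm, a, adh, censor, y, *covs = r
        d = dict(
            patient_id=pid, k=k, arm=arm, A=a, adherent=adh,
            censor=censor, Y=y,
        )
        for i, v in enumerate(covs):
            d[f"L_x{i}"] = float(v)
            d[f"M_x{i}"] = 1
        out.append(d)
    return pd.DataFrame(out)


def build_long(cfg, mode="PP", horizon=None, tables=None):
    """Raw tables -> PP/ITT person-interval dataset via the full pipeline
    path (new-user cohort, timelines, long build)."""
    from ttemul.cohort import (
        EligibilityCriteria,
        apply_eligibility,
        identify_new_users,
    )
    from ttemul.exposure import timelines_from_dispensings
    from ttemul.persontime import ProtocolSpec, build_long_dataset

    tables = generate_population(cfg) if tables is None else tables
    crit = EligibilityCriteria(compared_classes=list(cfg.med_classes))
    cand = identify_new_users(tables.dispensings, crit)
    cohort, _ = apply_eligibility(cand, tables.patients, crit)
    tls = timelines_from_dispensings(tables.dispensings)
    kinds = {
        c.name: "binary" if c.kind == "binary" else "continuous"
        for c in cfg.baseline_covariates
    }
    spec = ProtocolSpec(
        mode=mode, horizon_intervals=horizon or cfg.n_intervals
    )
    return build_long_dataset(
        cohort, tls, tables.measurements, tables.events, tables.patients,
        spec, kinds, compared_classes=cfg.med_classes,
        admin_end_day=cfg.horizon_days,
    )


def tmle_rd(long_df, g_learners, q_method, horizon, arms=("su", "glp1ra"),
            seed=0):
    """TMLE risk difference at one horizon with a chosen nuisance spec."""
    from ttemul.contrasts import risk_difference
    from ttemul.estimators import Regime, tmle_cuminc
    from ttemul.pipeline import fit_nuisances

    lib = LearnerLibrary(learners=g_learners, cv_folds=3, seed=seed)
    fits = fit_nuisances(long_df, "PP", lib)
    curves = [
        tmle_cuminc(
            long_df, fits, Regime(arm, True), [horizon],
            q_method=q_method, seed=seed,
        )
        for arm in arms
    ]
    return risk_difference(curves[0], curves[1])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
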