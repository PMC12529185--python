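"""Synthetic EHR generator with known causal ground truth.

Simulates raw longitudinal health-record tables (patients, dispensings,
covariate measurements, adverse events) from a :class:`ScenarioConfig`
world in which:

* treatment initiation is confounded by baseline covariates (softmax over
  per-class linear scores);
* time-varying covariates evolve first-order-Markov given their previous
  value and the exposure state of the previous interval;
* treatment continuation (refill behaviour) and right-censoring
  (disenrollment, non-cardiovascular death) depend on time-varying
  covariates, producing time-varying confounding and informative censoring;
* the discrete-time event hazard depends on current covariates and on the
  dispensing-derived exposure state -- the exposure that drives outcomes is
  exactly the coverage state the exposure engine reconstructs from the
  dispensing table (doubled days'-supply windows, 90-day gap bridging).

Ground truth is obtained by Monte-Carlo g-computation: the same simulator is
re-run with treatment forced to follow a regime (refills issued so coverage
is unbroken for sustained regimes) and censoring switched off.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    INTERVAL_DAYS,
    ConfigError,
    ScenarioConfig,
    expit,
    linear_predictor,
)
from .exposure import DEFAULT_MAX_GAP_DAYS

EVENT_TYPES = ("MI", "CVA")
CENSOR_CAUSES = ("disenrollment", "noncv_death")


@dataclass
class RawTables:
    """The four raw synthetic EHR tables (see module docstring)."""

    patients: pd.DataFrame
    dispensings: pd.DataFrame
    measurements: pd.DataFrame
    events: pd.DataFrame

    _FILES = ("patients", "dispensings", "measurements", "events")

    def write_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._FILES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read_csv(cls, in_dir) -> "RawTables":
        path = Path(in_dir)
        kw = {name: pd.read_csv(path / f"{name}.csv") for name in cls._FILES}
        if "death_day" in kw["patients"]:
            kw["patients"]["death_day"] = kw["patients"]["death_day"].astype(
                "Int64"
            )
        return cls(**kw)


@dataclass
class GroundTruth:
    """True counterfactual cumulative incidence per regime.

    ``curves`` maps a regime key ``(arm, sustained)`` to the per-interval
    risk F(k), k = 1..K; ``mc_se`` holds the binomial Monte-Carlo standard
    error of each point.
    """

    curves: dict[tuple[str, bool], np.ndarray]
    mc_se: dict[tuple[str, bool], np.ndarray]
    n_mc: int

    def risk(self, arm: str, sustained: bool = True) -> np.ndarray:
        return self.curves[(arm, sustained)]


def _draw_baseline(config: ScenarioConfig, rng, n: int) -> dict[str, np.ndarray]:
    values: dict[str, np.ndarray] = {}
    for spec in config.baseline_covariates:
        if spec.kind == "binary":
            values[spec.name] = (rng.random(n) < spec.params["p"]).astype(float)
        else:
            values[spec.name] = rng.normal(
                spec.params["mean"], spec.params["sd"], size=n
            )
    return values


def _assign_arms(config: ScenarioConfig, rng, L0) -> np.ndarray:
    n = len(next(iter(L0.values())))
    scores = np.zeros((n, config.n_classes))
    for j, med in enumerate(config.med_classes):
        scores[:, j] = linear_predictor(config.treatment_model.get(med, {}), L0)
    scores -= scores.max(axis=1, keepdims=True)
    probs = np.exp(scores)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _exposure_state(
    coverage_end, refilling, active_class, next_fill, day, n_classes,
    max_gap=DEFAULT_MAX_GAP_DAYS,
) -> np.ndarray:
    """(n, n_classes) 0/1 exposure at ``day`` under the coverage-and-gap rule.

    A class is exposed when the day is inside accumulated coverage, or when
    the patient is still refilling that class and the day falls inside an
    allowable (<= ``max_gap``-day) gap before the scheduled next fill.
    """
    covered = coverage_end > day
    n = coverage_end.shape[0]
    bridge = np.zeros_like(covered)
    rows = np.arange(n)
    ce = coverage_end[rows, active_class]
    ok = (
        refilling
        & (ce > 0)
        & (ce <= day)
        & (next_fill > day)
        & (next_fill - ce <= max_gap)
    )
    bridge[rows[ok], active_class[ok]] = True
    return (covered | bridge).astype(float)


def _simulate(
    config: ScenarioConfig,
    rng: np.random.Generator,
    n: int,
    forced_arm: int | None = None,
    force_adherence: bool = False,
    censoring: bool = True,
    collect: bool = True,
):
    """Shared simulation core for observed data and forced-regime oracles."""
    K = config.n_intervals
    classes = config.med_classes
    n_classes = config.n_classes
    spec = config.dispensing_spec

    L = _draw_baseline(config, rng, n)
    baseline = {name: v.copy() for name, v in L.items()}
    if forced_arm is None:
        arm = _assign_arms(config, rng, L)
    else:
        arm = np.full(n, forced_arm, dtype=int)

    active = np.ones(n, dtype=bool)
    refilling = np.ones(n, dtype=bool)
    active_class = arm.copy()
    next_fill = np.zeros(n, dtype=int)
    coverage_end = np.zeros((n, n_classes), dtype=int)
    enroll_end = np.full(n, config.horizon_days, dtype=int)
    death_day = np.full(n, -1, dtype=int)
    death_cause = np.full(n, "", dtype=object)
    event_interval = np.full(n, K + 1, dtype=int)  # first MACE interval

    fills: list[tuple[int, str, int, int]] = []
    meas_parts: list[tuple[np.ndarray, int, str]] = []
    meas_values: list[np.ndarray] = []
    events: list[tuple[int, int, str]] = []

    supplies = np.asarray(spec.supplies)
    supply_probs = np.asarray(spec.supply_probs)
    single_supply = len(spec.supplies) == 1

    dual = np.zeros(n, dtype=bool)
    if collect and config.dual_initiation_rate > 0:
        dual = rng.random(n) < config.dual_initiation_rate

    def draw_supply() -> int:
        if single_supply:
            return int(supplies[0])
        return int(supplies[int(rng.choice(len(supplies), p=supply_probs))])

    def emit_fills(idx: np.ndarray, limit_days: np.ndarray) -> None:
        """Emit due fills for patients ``idx`` up to each patient's limit."""
        for i in idx:
            while refilling[i] and next_fill[i] <= limit_days[i]:
                day = int(next_fill[i])
                supply = draw_supply()
                med_j = int(active_class[i])
                if collect:
                    fills.append((i, classes[med_j], day, supply))
                coverage_end[i, med_j] = max(
                    coverage_end[i, med_j], day + 2 * supply
                )
                if spec.refill_delay_max > spec.refill_delay_min:
                    delay = int(
                        rng.integers(
                            spec.refill_delay_min, spec.refill_delay_max + 1
                        )
                    )
                else:
                    delay = spec.refill_delay_min
                next_fill[i] = day + supply + delay

    tv_names = config.time_varying_names

    for k in range(K):
        d = k * INTERVAL_DAYS
        act = np.flatnonzero(active)
        if act.size == 0:
            break

        # 1. time-varying covariates evolve from (previous value, exposure
        #    state during the previous interval).
        if k > 0 and tv_names:
            if force_adherence:
                exp_prev = np.zeros((n, n_classes))
                exp_prev[np.arange(n), arm] = 1.0
            else:
                exp_prev = _exposure_state(
                    coverage_end, refilling, active_class, next_fill,
                    d - INTERVAL_DAYS, n_classes,
                )
            newL = {}
            for name in tv_names:
                dyn = config.covariate_dynamics[name]
                coefs = {
                    kk: v for kk, v in dyn.items()
                    if kk not in ("kind", "sd", "prev")
                }
                lp = linear_predictor(
                    coefs, L, exposure=exp_prev, exposure_classes=classes
                ) + dyn.get("prev", 0.0) * L[name]
                if dyn.get("kind", "binary") == "binary":
                    newL[name] = (rng.random(n) < expit(lp)).astype(float)
                else:
                    newL[name] = lp + rng.normal(0.0, dyn["sd"], size=n)
            for name, v in newL.items():
                L[name] = np.where(active, v, L[name])

        # 2. scheduled measurements (30-day cadence; baseline measures all
        #    covariates, later intervals the time-varying ones).
        if collect:
            names = config.covariate_names if k == 0 else tv_names
            for name in names:
                observed = rng.random(n) < 1.0 - config.missingness_rate
                idx = act[observed[act]]
                if idx.size:
                    meas_parts.append((idx, d, name))
                    meas_values.append(L[name][idx])

        # 3. treatment continuation decisions (latent refill behaviour).
        if k > 0 and not force_adherence:
            ref = act[refilling[act]]
            if ref.size:
                p_disc = expit(
                    linear_predictor(config.continuation_model["discontinue"], L)
                )
                stop = rng.random(n) < p_disc
                p_cross = expit(
                    linear_predictor(config.continuation_model["crossover"], L)
                )
                cross = rng.random(n) < p_cross
                for i in ref:
                    if stop[i]:
                        refilling[i] = False
                    elif cross[i] and n_classes > 1:
                        others = [
                            j for j in range(n_classes) if j != active_class[i]
                        ]
                        active_class[i] = others[
                            int(rng.integers(0, len(others)))
                        ]
                        next_fill[i] = d

        # 4. fills due at or before today, then today's exposure state.
        if force_adherence:
            exposure = np.zeros((n, n_classes))
            exposure[np.arange(n), arm] = 1.0
        else:
            emit_fills(act[refilling[act]], np.full(n, d))
            if k == 0 and collect and dual.any():
                for i in act[dual[act]]:
                    others = [j for j in range(n_classes) if j != arm[i]]
                    med_j = others[int(rng.integers(0, len(others)))]
                    supply = draw_supply()
                    fills.append((i, classes[med_j], 0, supply))
                    coverage_end[i, med_j] = max(
                        coverage_end[i, med_j], 2 * supply
                    )
            exposure = _exposure_state(
                coverage_end, refilling, active_class, next_fill, d, n_classes
            )

        # 5. censoring decided before the interval's event draw (canonical
        #    longitudinal ordering L_k -> C_k -> Y_k): a censored patient
        #    contributes no event this interval, so the event probability
        #    among uncensored at-risk patients equals the structural hazard.
        terminal_day = np.full(n, config.horizon_days, dtype=int)
        ended = np.zeros(n, dtype=bool)
        if censoring:
            p_dth = expit(
                linear_predictor(config.censoring_model["noncv_death"], L)
            )
            p_dis = expit(
                linear_predictor(config.censoring_model["disenrollment"], L)
            )
            u_dth = rng.random(n)
            u_dis = rng.random(n)
            u_unk = rng.random(n)
            cens_days = d + rng.integers(0, INTERVAL_DAYS, size=n)
            for i in act:
                if u_dth[i] < p_dth[i]:
                    death_day[i] = int(cens_days[i])
                    death_cause[i] = (
                        "unknown"
                        if u_unk[i] < config.unknown_death_frac
                        else "noncardiovascular"
                    )
                    enroll_end[i] = int(cens_days[i])
                    terminal_day[i] = int(cens_days[i])
                    ended[i] = True
                elif u_dis[i] < p_dis[i]:
                    enroll_end[i] = int(cens_days[i])
                    terminal_day[i] = int(cens_days[i])
                    ended[i] = True

        # 6. event draw among the uncensored.
        p_event = expit(
            linear_predictor(
                config.hazard_model, L, exposure=exposure,
                exposure_classes=classes,
            )
        )
        hit_event = rng.random(n) < p_event
        ev = act[hit_event[act] & ~ended[act]]
        if ev.size:
            ev_days = d + rng.integers(0, INTERVAL_DAYS, size=n)
            kinds = list(config.event_type_probs)
            kp = np.asarray([config.event_type_probs[kk] for kk in kinds])
            for i in ev:
                kind = kinds[int(rng.choice(len(kinds), p=kp))]
                day_e = int(ev_days[i])
                if kind == "cv_death":
                    death_day[i] = day_e
                    death_cause[i] = "cardiovascular"
                    enroll_end[i] = day_e
                elif collect:
                    events.append((i, day_e, kind))
                event_interval[i] = k
                terminal_day[i] = day_e
                ended[i] = True

        # 7. remaining fills this interval, truncated at the terminal day so
        #    no dispensing postdates death or disenrollment.
        if not force_adherence:
            limits = np.minimum(d + INTERVAL_DAYS - 1, terminal_day)
            emit_fills(act[refilling[act]], limits)

        active[ended] = False

    result = {
        "arm": arm,
        "event_interval": event_interval,
        "enroll_end": enroll_end,
        "death_day": death_day,
        "death_cause": death_cause,
        "baseline": baseline,
    }
    if collect:
        meas_frames = []
        for (idx, day, name), vals in zip(meas_parts, meas_values):
            meas_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": idx,
                        "day": day,
                        "covariate": name,
                        "value": vals,
                    }
                )
            )
        measurements = (
            pd.concat(meas_frames, ignore_index=True)
            .sort_values(["patient_id", "day", "covariate"], kind="stable")
            .reset_index(drop=True)
            if meas_frames
            else pd.DataFrame(columns=["patient_id", "day", "covariate", "value"])
        )
        result["tables"] = _build_tables(
            config, baseline, arm, enroll_end, death_day, death_cause,
            fills, measurements, events,
        )
    return result


def _build_tables(
    config, baseline, arm, enroll_end, death_day, death_cause,
    fills, measurements, events,
) -> RawTables:
    n = len(arm)
    patients = pd.DataFrame({"patient_id": np.arange(n)})
    for name, vals in baseline.items():
        patients[name] = vals
    patients["enrollment_start"] = 0
    patients["enrollment_end"] = enroll_end
    patients["death_day"] = pd.array(
        [d if d >= 0 else pd.NA for d in death_day], dtype="Int64"
    )
    patients["death_cause"] = [c if c else pd.NA for c in death_cause]
    dispensings = (
        pd.DataFrame(
            fills,
            columns=["patient_id", "med_class", "dispense_day", "days_supply"],
        )
        .sort_values(["patient_id", "dispense_day", "med_class"], kind="stable")
        .reset_index(drop=True)
    )
    ev = pd.DataFrame(events, columns=["patient_id", "day", "event_type"])
    return RawTables(
        patients=patients,
        dispensings=dispensings,
        measurements=measurements,
        events=ev,
    )


def generate_population(config: ScenarioConfig) -> RawTables:
    """Generate the four raw tables; bit-for-bit reproducible given the seed."""
    rng = np.random.default_rng([config.seed, 0x5EED])
    sim = _simulate(config, rng, config.n_patients, collect=True)
    return sim["tables"]


def true_counterfactual_risk(
    config: ScenarioConfig,
    regime,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> GroundTruth:
    """Monte-Carlo g-computation oracle for one static regime.

    Simulates ``n_mc`` patients with treatment forced to follow ``regime``
    (an object with ``arm`` and ``sustained`` attributes) and censoring
    switched off; returns the empirical counterfactual cumulative incidence
    per 30-day interval with its binomial Monte-Carlo SE.
    """
    if n_mc < 10_000:
        raise ConfigError("n_mc must be at least 10000 for a usable oracle")
    if regime.arm not in config.med_classes:
        raise ConfigError(
            f"regime arm {regime.arm!r} not among {config.med_classes}"
        )
    arm_idx = config.med_classes.index(regime.arm)
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, 0x06AC1E, arm_idx,
         int(bool(regime.sustained))]
    )
    sim = _simulate(
        config, rng, n_mc,
        forced_arm=arm_idx,
        force_adherence=bool(regime.sustained),
        censoring=False,
        collect=False,
    )
    K = config.n_intervals
    ev = sim["event_interval"]
    F = np.array([(ev < k).mean() for k in range(1, K + 1)])
    se = np.sqrt(np.clip(F * (1 - F), 1e-12, None) / n_mc)
    key = (regime.arm, bool(regime.sustained))
    return GroundTruth(curves={key: F}, mc_se={key: se}, n_mc=n_mc)


def ground_truth(
    config: ScenarioConfig, regimes, n_mc: int = 100_000, seed=None
) -> GroundTruth:
    """Oracle curves for several regimes, merged into one GroundTruth."""
    curves, ses = {}, {}
    for regime in regimes:
        gt = true_counterfactual_risk(config, regime, n_mc=n_mc, seed=seed)
        curves.update(gt.curves)
        ses.update(gt.mc_se)
    return GroundTruth(curves=curves, mc_se=ses, n_mc=n_mc)
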