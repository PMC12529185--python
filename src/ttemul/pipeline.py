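"""End-to-end emulation: raw tables -> attrition -> curves -> contrasts.

``run_emulation`` wires the pipeline together for one emulated trial:
new-user cohort construction with washout and eligibility attrition,
dispensing-derived exposure timelines, the 30-day person-interval dataset
under PP and/or ITT follow-up, super-learner propensities for initiation /
continuation / each censoring cause, cumulative inverse-probability
weights, and unadjusted, IPW and TMLE cumulative incidence curves with
two-arm contrasts.  Subgroup analyses re-run the whole estimation chain --
including refitting every propensity model -- inside the subgroup, and
complementary subgroup pairs get an effect-modification test on the PP
risk difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import (
    AttritionReport,
    EligibilityCriteria,
    apply_eligibility,
    identify_new_users,
)
from .config import ScenarioConfig
from .contrasts import ContrastResult, contrast_curves, effect_modification_test, ipw_hazard_ratio
from .estimators import (
    CumulativeIncidenceCurve,
    Regime,
    product_limit_cuminc,
    tmle_cuminc,
    unit_weights,
)
from .exposure import timelines_from_dispensings
from .nuisance import (
    IPW_TRUNCATION,
    TMLE_CAP,
    LearnerLibrary,
    TruncationSpec,
    cumulative_weights,
    fit_propensity_series,
)
from .persontime import (
    OutcomeDefinition,
    ProtocolSpec,
    build_long_dataset,
    followup_end_counts,
)
from .simulate import RawTables, generate_population


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class EmulationConfig:
    """Configuration of one emulated target trial on synthetic data."""

    scenario: ScenarioConfig
    treated: str | None = None
    control: str | None = None
    arms: tuple[str, ...] | None = None  # arms to estimate; default the pair
    modes: tuple[str, ...] = ("PP", "ITT")
    horizon_intervals: int | None = None
    outcome: OutcomeDefinition = field(default_factory=OutcomeDefinition)
    estimators: tuple[str, ...] = ("unadjusted", "ipw", "tmle")
    library: LearnerLibrary | None = None
    q_method: str = "lasso"
    ipw_truncation: TruncationSpec = IPW_TRUNCATION
    tmle_cap: float = TMLE_CAP
    min_events: int = 25
    exclusion_predicates: tuple = ()
    subgroup_splits: dict[str, Callable] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treated is None:
            self.treated = self.scenario.med_classes[0]
        if self.control is None:
            self.control = self.scenario.med_classes[1]
        if self.arms is None:
            self.arms = (self.treated, self.control)
        if self.horizon_intervals is None:
            self.horizon_intervals = min(self.scenario.n_intervals, 30)
        if self.library is None:
            self.library = LearnerLibrary(
                learners=("intercept", "glm", "lasso"),
                cv_folds=5,
                seed=self.seed,
            )


@dataclass
class PipelineState:
    """Fitted state of one (mode, cohort) analysis, reusable by the
    sensitivity suite without refitting nuisance models."""

    mode: str
    long_df: pd.DataFrame
    fits: dict
    weights: np.ndarray
    weight_info: dict
    horizon: int
    treated: str
    control: str
    q_method: str
    tmle_cap: float
    seed: int


@dataclass
class EmulationReport:
    attrition: AttritionReport
    curves: dict[tuple[str, str, str], CumulativeIncidenceCurve]
    contrasts: dict[tuple[str, str], ContrastResult]
    subgroup_contrasts: dict[str, dict[tuple[str, str], ContrastResult]]
    em_tests: dict[str, tuple[float, float]]
    states: dict[str, PipelineState]
    weight_diagnostics: dict[str, dict]

    def contrast_table(self) -> pd.DataFrame:
        """Report-shaped contrast table (one row per analysis)."""
        rows = []
        for (mode, estimator), c in self.contrasts.items():
            row = c.to_dict()
            row["subgroup"] = "all"
            rows.append(self._fill_risks(row, mode, estimator))
        for label, contrasts in self.subgroup_contrasts.items():
            for (mode, estimator), c in contrasts.items():
                row = c.to_dict()
                row["subgroup"] = label
                rows.append(row)
        return pd.DataFrame(rows)

    def _fill_risks(self, row, mode, estimator):
        kt = (mode, estimator, row["treated"])
        kc = (mode, estimator, row["control"])
        if kt in self.curves and kc in self.curves:
            row["risk_treated"] = float(self.curves[kt].F[-1])
            row["risk_control"] = float(self.curves[kc].F[-1])
        return row

    def to_markdown(self) -> str:
        lines = ["# Emulated-trial report", "", "## Attrition", ""]
        lines.append("```\n" + self.attrition.to_text() + "\n```")
        lines += ["", "## Contrasts (treated vs control)", ""]
        tbl = self.contrast_table()
        lines.append(tbl.to_markdown(index=False))
        if self.em_tests:
            lines += ["", "## Effect-modification tests (PP)", ""]
            for label, (z, p) in self.em_tests.items():
                lines.append(f"- {label}: z = {z:.3f}, p = {p:.4f}")
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.attrition.to_frame().to_csv(out / "attrition.csv", index=False)
        self.contrast_table().to_csv(out / "contrasts.csv", index=False)
        curve_rows = []
        for (mode, estimator, arm), curve in self.curves.items():
            for k in range(curve.horizon):
                curve_rows.append(
                    {
                        "mode": mode, "estimator": estimator, "arm": arm,
                        "interval": k + 1, "F": curve.F[k],
                        "se": curve.se[k],
                        "lcl": curve.F[k] - 1.96 * curve.se[k],
                        "ucl": curve.F[k] + 1.96 * curve.se[k],
                    }
                )
        pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False)
        with open(out / "report.md", "w") as fh:
            fh.write(self.to_markdown())


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def fit_nuisances(
    long_df: pd.DataFrame,
    mode: str,
    library: LearnerLibrary,
    min_events: int = 25,
) -> dict:
    """All propensity fits needed for weighting a long dataset."""
    fits = {}
    for arm in sorted(long_df["arm"].unique()):
        fits[f"initiation:{arm}"] = fit_propensity_series(
            long_df, "initiation", library, arm=str(arm),
            min_events=min_events,
        )
    for cause in ("disenrollment", "noncv_death", "unknown_death"):
        if (long_df["censor"] == cause).any():
            fits[f"censor:{cause}"] = fit_propensity_series(
                long_df, f"censor:{cause}", library, min_events=min_events
            )
    if mode == "PP":
        fits["continuation"] = fit_propensity_series(
            long_df, "continuation", library, min_events=min_events
        )
    return fits


def analyze_long_dataset(
    long_df: pd.DataFrame,
    mode: str,
    treated: str,
    control: str,
    horizon: int,
    config: EmulationConfig,
) -> tuple[
    PipelineState,
    dict[tuple[str, str], CumulativeIncidenceCurve],
    dict[str, ContrastResult],
]:
    """Nuisance fitting, weighting, estimation and contrasts for one
    long dataset (used for both the full cohort and each subgroup)."""
    fits = fit_nuisances(long_df, mode, config.library, config.min_events)
    weights, winfo = cumulative_weights(
        long_df, fits, mode=mode, truncation=config.ipw_truncation
    )
    state = PipelineState(
        mode=mode, long_df=long_df, fits=fits, weights=weights,
        weight_info=winfo, horizon=horizon, treated=treated,
        control=control, q_method=config.q_method,
        tmle_cap=config.tmle_cap, seed=config.seed,
    )
    sustained = mode == "PP"
    curves: dict[tuple[str, str], CumulativeIncidenceCurve] = {}
    for arm in config.arms:
        regime = Regime(arm=arm, sustained=sustained)
        if "unadjusted" in config.estimators:
            curves[("unadjusted", arm)] = product_limit_cuminc(
                long_df, unit_weights(long_df, mode), regime,
                horizon=horizon, label="unadjusted",
            )
        if "ipw" in config.estimators:
            curves[("ipw", arm)] = product_limit_cuminc(
                long_df, weights, regime, horizon=horizon, label="ipw"
            )
        if "tmle" in config.estimators:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curves[("tmle", arm)] = tmle_cuminc(
                    long_df, fits, regime, horizons=list(range(1, horizon + 1)),
                    q_method=config.q_method, tmle_cap=config.tmle_cap,
                    seed=config.seed,
                )
    contrasts: dict[str, ContrastResult] = {}
    for estimator in config.estimators:
        c1, c0 = curves[(estimator, treated)], curves[(estimator, control)]
        hr = hr_ci = None
        pair_events = long_df[long_df["arm"].isin((treated, control))]
        if estimator == "ipw" and (pair_events["Y"].groupby(
            pair_events["arm"]
        ).sum() > 0).all():
            try:
                hr, hr_ci = ipw_hazard_ratio(
                    long_df, weights, (treated, control)
                )
            except Exception:  # noqa: BLE001 - HR is a secondary measure
                hr = hr_ci = None
        contrasts[estimator] = contrast_curves(
            c1, c0, mode=mode, hr=hr, hr_ci=hr_ci
        )
    return state, curves, contrasts


def run_emulation(
    config: EmulationConfig, tables: RawTables | None = None
) -> EmulationReport:
    """Run one full emulated trial; deterministic given the configuration."""
    scenario = config.scenario
    if tables is None:
        tables = _stage("simulate")(generate_population)(scenario)

    criteria = EligibilityCriteria(
        compared_classes=list(scenario.med_classes),
        exclusion_predicates=list(config.exclusion_predicates),
    )
    candidates = _stage("new_users")(identify_new_users)(
        tables.dispensings, criteria
    )
    cohort, attrition = _stage("eligibility")(apply_eligibility)(
        candidates, tables.patients, criteria
    )
    cohort = cohort[cohort["index_class"].isin(config.arms)]
    timelines = _stage("exposure")(timelines_from_dispensings)(
        tables.dispensings
    )

    covariate_kinds = {
        c.name: ("binary" if c.kind == "binary" else "continuous")
        for c in scenario.baseline_covariates
    }
    horizon = config.horizon_intervals

    curves: dict[tuple[str, str, str], CumulativeIncidenceCurve] = {}
    all_contrasts: dict[tuple[str, str], ContrastResult] = {}
    states: dict[str, PipelineState] = {}
    weight_diag: dict[str, dict] = {}
    long_by_mode: dict[str, pd.DataFrame] = {}

    for mode in config.modes:
        spec = ProtocolSpec(
            mode=mode, horizon_intervals=horizon, outcome=config.outcome
        )
        long_df = _stage(f"person_time[{mode}]")(build_long_dataset)(
            cohort, timelines, tables.measurements, tables.events,
            tables.patients, spec, covariate_kinds,
            compared_classes=scenario.med_classes,
            admin_end_day=scenario.horizon_days,
        )
        long_by_mode[mode] = long_df
        state, mode_curves, mode_contrasts = _stage(f"estimate[{mode}]")(
            analyze_long_dataset
        )(long_df, mode, config.treated, config.control, horizon, config)
        states[mode] = state
        weight_diag[mode] = state.weight_info
        for (estimator, arm), curve in mode_curves.items():
            curves[(mode, estimator, arm)] = curve
        for estimator, contrast in mode_contrasts.items():
            all_contrasts[(mode, estimator)] = contrast

    if "PP" in long_by_mode:
        attrition.followup_end_counts = followup_end_counts(long_by_mode["PP"])

    # subgroup analyses: re-run estimation (refitting all propensities)
    subgroup_contrasts: dict[str, dict] = {}
    em_tests: dict[str, tuple[float, float]] = {}
    pat_indexed = tables.patients.set_index("patient_id")
    for label, split in config.subgroup_splits.items():
        flags = pat_indexed.loc[cohort["patient_id"]].apply(split, axis=1)
        for side, side_label in ((True, label), (False, f"not_{label}")):
            sub_cohort = cohort[flags.to_numpy() == side]
            if sub_cohort.empty:
                continue
            sub_results: dict[tuple[str, str], ContrastResult] = {}
            for mode in config.modes:
                sub_long = long_by_mode[mode][
                    long_by_mode[mode]["patient_id"].isin(
                        set(sub_cohort["patient_id"])
                    )
                ].reset_index(drop=True)
                _, _, sub_contrasts = _stage(
                    f"subgroup[{side_label},{mode}]"
                )(analyze_long_dataset)(
                    sub_long, mode, config.treated, config.control,
                    horizon, config,
                )
                for estimator, contrast in sub_contrasts.items():
                    sub_results[(mode, estimator)] = contrast
            subgroup_contrasts[side_label] = sub_results
        # effect-modification test on the PP primary-estimator RD
        primary = "tmle" if "tmle" in config.estimators else config.estimators[-1]
        key = ("PP", primary)
        a = subgroup_contrasts.get(label, {}).get(key)
        b = subgroup_contrasts.get(f"not_{label}", {}).get(key)
        if a is not None and b is not None:
            em_tests[label] = effect_modification_test(
                a.rd, a.rd_se, b.rd, b.rd_se
            )

    return EmulationReport(
        attrition=attrition,
        curves=curves,
        contrasts=all_contrasts,
        subgroup_contrasts=subgroup_contrasts,
        em_tests=em_tests,
        states=states,
        weight_diagnostics=weight_diag,
    )
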