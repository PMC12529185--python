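"""Discrete-time person-interval analysis dataset.

Collapses raw tables into the long format used by all estimators: one row
per patient per 30-day interval from the index date, carrying the exposure
indicator, imputed covariates with measurement indicators, the censoring
cause, and the outcome indicator.  Follow-up ends at the earliest of:
outcome, death-censoring (non-cardiovascular or unknown cause),
disenrollment, administrative end of data, the protocol horizon, and -- in
per-protocol mode -- artificial censoring at the interval containing the
first treatment-protocol deviation.  Within an interval the documented
precedence is outcome > death censoring > disenrollment > administrative
end > artificial per-protocol censoring.

Missing covariates are encoded with the missingness-indicator approach:
unobserved baseline values are replaced by the cohort mode (categorical) or
mean (continuous) of observed baselines, unobserved time-varying values by
the last observed value, otherwise the imputed baseline; a 0/1 measurement
indicator per covariate per interval is carried alongside for adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import INTERVAL_DAYS
from .exposure import ExposureTimeline, detect_deviation

CENSOR_NONE = "none"
CENSOR_CAUSES = (
    "noncv_death",
    "unknown_death",
    "disenrollment",
    "admin_end",
    "artificial_pp",
)
# lower rank wins a within-interval tie; outcome (rank -1) beats them all
_PRECEDENCE = {
    "outcome": -1,
    "noncv_death": 0,
    "unknown_death": 0,
    "disenrollment": 1,
    "admin_end": 2,
    "artificial_pp": 3,
}

_DEATH_CHANNEL = {"noncardiovascular": "noncv_death", "unknown": "unknown_death"}


class PersonTimeError(ValueError):
    """Raised for inconsistent person-time input."""


@dataclass(frozen=True)
class OutcomeDefinition:
    """Composite event definition: which event types and death causes count.

    The primary 3-point MACE composite is nonfatal MI, nonfatal stroke and
    cardiovascular death; an expanded variant adds further death causes.
    """

    event_types: frozenset = frozenset({"MI", "CVA"})
    death_causes: frozenset = frozenset({"cardiovascular"})

    def __post_init__(self) -> None:
        if not self.event_types and not self.death_causes:
            raise PersonTimeError("outcome definition matches nothing")


@dataclass
class ProtocolSpec:
    """Follow-up protocol: PP (sustained use) or ITT (initiation only)."""

    mode: str = "PP"
    horizon_intervals: int = 30
    outcome: OutcomeDefinition = field(default_factory=OutcomeDefinition)

    def __post_init__(self) -> None:
        if self.mode not in ("PP", "ITT"):
            raise PersonTimeError(f"mode must be PP or ITT, got {self.mode!r}")
        if self.horizon_intervals < 1:
            raise PersonTimeError("horizon_intervals must be >= 1")


def encode_missingness(
    measurements: pd.DataFrame,
    index_days: pd.Series,
    covariate_kinds: dict[str, str],
    horizon_intervals: int,
    baseline_window_days: int = 365,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Impute covariates on the 30-day grid and build measurement indicators.

    ``index_days`` maps patient_id -> index day.  Returns ``(L, M)`` where
    ``L[name]`` is a (patient x interval) frame of imputed values and
    ``M[name]`` the matching 0/1 observed-this-interval indicators.
    Measurements up to ``baseline_window_days`` before the index contribute
    to the baseline value (but not to the interval-0 indicator); within an
    interval the latest measurement wins.
    """
    pids = index_days.index
    K = horizon_intervals
    L: dict[str, pd.DataFrame] = {}
    M: dict[str, pd.DataFrame] = {}

    df = measurements.merge(
        index_days.rename("index_day"), left_on="patient_id", right_index=True
    )
    df = df[df["patient_id"].isin(set(pids))]
    df["rel_day"] = df["day"] - df["index_day"]
    df = df[
        (df["rel_day"] >= -baseline_window_days)
        & (df["rel_day"] < K * INTERVAL_DAYS)
    ]
    df["k"] = df["rel_day"] // INTERVAL_DAYS
    # pre-index measurements feed the baseline (interval 0) value slot
    df["k_eff"] = df["k"].clip(lower=0)
    df = df.sort_values(["patient_id", "covariate", "day"], kind="stable")

    for name, kind in covariate_kinds.items():
        sub = df[df["covariate"] == name]
        vals = (
            sub.pivot_table(
                index="patient_id", columns="k_eff", values="value",
                aggfunc="last",
            )
            .reindex(index=pids, columns=range(K))
        )
        obs = (
            sub[sub["k"] >= 0]
            .pivot_table(
                index="patient_id", columns="k", values="value", aggfunc="size"
            )
            .reindex(index=pids, columns=range(K))
        )
        M[name] = obs.notna().astype(int)

        baseline = vals[0]
        if baseline.notna().sum() == 0:
            raise PersonTimeError(
                f"covariate {name!r}: no observed baseline values cohort-wide,"
                " nothing to impute from"
            )
        if kind in ("categorical", "binary"):
            fill = baseline.mode().iloc[0]
        elif kind == "continuous":
            fill = baseline.mean()
        else:
            raise PersonTimeError(
                f"covariate {name!r}: unknown kind {kind!r}"
            )
        vals = vals.ffill(axis=1)
        vals[0] = vals[0].fillna(fill)
        L[name] = vals.ffill(axis=1)
    return L, M


def build_long_dataset(
    cohort: pd.DataFrame,
    timelines: dict[object, dict[str, ExposureTimeline]],
    measurements: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    spec: ProtocolSpec,
    covariate_kinds: dict[str, str],
    compared_classes: tuple[str, ...] | None = None,
    admin_end_day: int | None = None,
    baseline_window_days: int = 365,
) -> pd.DataFrame:
    """One row per patient per 30-day interval, PP or ITT convention.

    ``cohort`` must carry ``patient_id, index_day, index_class``; interval k
    covers follow-up days ``[30k, 30(k+1))`` from the index date.
    """
    pat = patients.set_index("patient_id", drop=False)
    missing = set(cohort["patient_id"]) - set(pat.index)
    if missing:
        raise PersonTimeError(f"cohort patients without records: {missing}")
    if compared_classes is None:
        compared_classes = tuple(sorted(cohort["index_class"].unique()))
    H = spec.horizon_intervals
    outcome = spec.outcome

    index_days = cohort.set_index("patient_id")["index_day"]
    L, M = encode_missingness(
        measurements, index_days, covariate_kinds, H, baseline_window_days
    )

    ev = events[events["event_type"].isin(outcome.event_types)]
    ev_by_pid = {pid: grp for pid, grp in ev.groupby("patient_id")}

    rows: list[dict] = []
    for cand in cohort.itertuples(index=False):
        pid, index_day, arm = (
            cand.patient_id, int(cand.index_day), cand.index_class,
        )
        prow = pat.loc[pid]
        # (k, precedence, kind, day) -- real causes resolve by interval with
        # the documented precedence; artificial PP censoring resolves at day
        # level against them (its day is exact coverage arithmetic and the
        # deviating interval contributes no at-risk time).
        candidates: list[tuple[int, int, str, int]] = []

        # outcome: earliest qualifying event or qualifying-cause death
        out_days = []
        grp = ev_by_pid.get(pid)
        if grp is not None:
            if (grp["day"] < index_day).any():
                raise PersonTimeError(
                    f"patient {pid!r}: outcome event before index day"
                )
            out_days.extend(int(d) for d in grp["day"])
        death_day = prow.get("death_day")
        death_cause = prow.get("death_cause")
        has_death = pd.notna(death_day)
        if has_death and str(death_cause) in outcome.death_causes:
            out_days.append(int(death_day))
        if out_days:
            out_day = min(out_days)
            k_out = (out_day - index_day) // INTERVAL_DAYS
            if k_out < 0:
                raise PersonTimeError(
                    f"patient {pid!r}: outcome before index day"
                )
            if k_out < H:
                candidates.append(
                    (k_out, _PRECEDENCE["outcome"], "outcome", out_day)
                )

        # death from a non-qualifying cause is a censoring channel
        if has_death and str(death_cause) not in outcome.death_causes:
            channel = _DEATH_CHANNEL.get(str(death_cause), "noncv_death")
            k_d = (int(death_day) - index_day) // INTERVAL_DAYS
            if 0 <= k_d < H:
                candidates.append(
                    (k_d, _PRECEDENCE[channel], channel, int(death_day))
                )

        # disenrollment before the administrative end of data
        enroll_end = int(prow["enrollment_end"])
        cal_end = admin_end_day if admin_end_day is not None else enroll_end + 1
        if enroll_end < cal_end and not (
            has_death and int(death_day) <= enroll_end
        ):
            k_c = (enroll_end - index_day) // INTERVAL_DAYS
            if 0 <= k_c < H:
                candidates.append(
                    (k_c, _PRECEDENCE["disenrollment"], "disenrollment",
                     enroll_end)
                )

        # administrative end of data: only a partially observed interval is
        # marked (and dropped from risk); follow-up that runs through the
        # full horizon ends without a terminal mark and is tallied as
        # administrative end in reporting.
        if admin_end_day is not None:
            k_a = (admin_end_day - index_day) // INTERVAL_DAYS
            if k_a < H:
                candidates.append(
                    (k_a, _PRECEDENCE["admin_end"], "admin_end",
                     admin_end_day)
                )

        # protocol deviation (dispensing-derived)
        tls = timelines.get(pid, {})
        dev_day, dev_kind = detect_deviation(
            tls, arm, compared_classes, index_day
        )
        k_dev = (
            (dev_day - index_day) // INTERVAL_DAYS
            if dev_kind != "none"
            else H
        )

        if candidates:
            k_o, _, kind_o, day_o = min(candidates)
        else:
            k_o, kind_o, day_o = H, "completed", None
        if spec.mode == "PP" and k_dev < H and (
            k_dev < k_o or (k_dev == k_o and dev_day <= day_o)
        ):
            k_term, kind_term = k_dev, "artificial_pp"
        elif k_o < H:
            k_term, kind_term = k_o, kind_o
        else:
            k_term, kind_term = H - 1, "completed"
        index_tl = tls[arm]
        for k in range(k_term + 1):
            terminal = k == k_term
            y = int(terminal and kind_term == "outcome")
            censor = (
                kind_term
                if terminal and kind_term not in ("outcome", "completed")
                else CENSOR_NONE
            )
            # outcome precedence keeps a same-interval deviator at risk
            adherent = k < k_dev or (k == k_dev and y == 1)
            row = {
                "patient_id": pid,
                "k": k,
                "arm": arm,
                "A": int(index_tl.covered_on(index_day + k * INTERVAL_DAYS)),
                "adherent": bool(adherent),
                "censor": censor,
                "Y": y,
            }
            for name in covariate_kinds:
                row[f"L_{name}"] = L[name].at[pid, k]
                row[f"M_{name}"] = int(M[name].at[pid, k])
            rows.append(row)

    long_df = pd.DataFrame(rows)
    if long_df.empty:
        raise PersonTimeError("empty cohort produced no person-time")
    return long_df.sort_values(["patient_id", "k"], kind="stable").reset_index(
        drop=True
    )


def followup_end_counts(long_df: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per-arm counts of how follow-up ended (outcome, each censoring cause,
    administrative end for patients who completed the horizon unmarked)."""
    out: dict[str, dict[str, int]] = {}
    last = long_df.sort_values("k").groupby("patient_id").tail(1)
    for arm, grp in last.groupby("arm"):
        counts: dict[str, int] = {}
        counts["outcome"] = int((grp["Y"] == 1).sum())
        for cause in CENSOR_CAUSES:
            counts[cause] = int((grp["censor"] == cause).sum())
        counts["admin_end"] += int(
            ((grp["Y"] == 0) & (grp["censor"] == CENSOR_NONE)).sum()
        )
        out[str(arm)] = counts
    return out


def write_long_dataset(long_df: pd.DataFrame, path) -> None:
    """Interchange format between pipeline stages: one wide CSV."""
    long_df.to_csv(path, index=False)


def read_long_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path)
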