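"""Two-arm contrasts of counterfactual cumulative incidence curves.

Effect measures follow the emulated-trial convention: the risk difference
(RD) at the reporting horizon, the average risk difference (ARD) over
follow-up (difference in area under two cumulative incidence curves,
reported per interval of follow-up so it shares the risk scale), the number
needed to treat (NNT = 1/RD, suppressed when the RD CI crosses 0), and a
secondary IPW hazard ratio from a weighted pooled logistic model.  Because
both arms are estimated on the same cohort, contrast SEs difference the
per-patient influence curves rather than assuming independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimators import CumulativeIncidenceCurve, EstimatorError, ic_variance


@dataclass
class ContrastResult:
    """RD / ARD / NNT / HR between two arms with IC-based inference."""

    arm_treated: str
    arm_control: str
    horizon: int
    rd: float
    rd_se: float
    rd_ci: tuple[float, float]
    rd_p: float
    ard: float
    ard_se: float
    ard_ci: tuple[float, float]
    ard_p: float
    nnt: int | None
    estimator: str
    mode: str
    hr: float | None = None
    hr_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "treated": self.arm_treated,
            "control": self.arm_control,
            "estimator": self.estimator,
            "mode": self.mode,
            "risk_treated": None,
            "risk_control": None,
            "rd": self.rd,
            "rd_lcl": self.rd_ci[0],
            "rd_ucl": self.rd_ci[1],
            "rd_p": self.rd_p,
            "nnt": self.nnt,
            "ard": self.ard,
            "ard_lcl": self.ard_ci[0],
            "ard_ucl": self.ard_ci[1],
            "ard_p": self.ard_p,
            "hr": self.hr,
        }


def _check_aligned(curve1, curve0, horizon=None):
    if curve1.horizon != curve0.horizon:
        raise EstimatorError("curves estimated on different horizon grids")
    if not np.array_equal(curve1.patient_ids, curve0.patient_ids):
        raise EstimatorError("curves estimated on different cohorts")
    K = curve1.horizon
    horizon = K if horizon is None else horizon
    if not 1 <= horizon <= K:
        raise EstimatorError(f"horizon {horizon} outside 1..{K}")
    return horizon


def _p_from(est, se):
    if se == 0:
        return 1.0 if est == 0 else 0.0
    return float(2 * norm.sf(abs(est) / se))


def risk_difference(
    curve1: CumulativeIncidenceCurve,
    curve0: CumulativeIncidenceCurve,
    horizon: int | None = None,
):
    """RD at the reporting horizon with IC-difference SE.

    Returns ``(rd, se, (lcl, ucl), p)``.
    """
    K = _check_aligned(curve1, curve0, horizon)
    rd = float(curve1.F[K - 1] - curve0.F[K - 1])
    ic = curve1.ic[:, K - 1] - curve0.ic[:, K - 1]
    se, ci = ic_variance(ic, estimate=rd)
    return rd, se, ci, _p_from(rd, se)


def average_risk_difference(
    curve1: CumulativeIncidenceCurve, curve0: CumulativeIncidenceCurve
):
    """ARD: time-averaged per-interval risk difference (area between step
    curves divided by follow-up length).  Returns ``(ard, se, ci, p)``."""
    _check_aligned(curve1, curve0)
    diffs = curve1.F - curve0.F
    ard = float(diffs.mean())
    ic = (curve1.ic - curve0.ic).mean(axis=1)
    se, ci = ic_variance(ic, estimate=ard)
    return ard, se, ci, _p_from(ard, se)


def nnt(rd: float, ci: tuple[float, float]) -> int | None:
    """NNT = 1/|RD| rounded to the nearest integer, reported only when the
    CI excludes 0 (mirroring the NA convention for nonsignificant RDs)."""
    if not np.isfinite(rd):
        raise EstimatorError("rd must be finite")
    if rd == 0 or ci[0] <= 0 <= ci[1]:
        return None
    return int(round(1.0 / abs(rd)))


def ipw_hazard_ratio(
    long_df: pd.DataFrame,
    weights: np.ndarray,
    arms: tuple[str, str],
):
    """Secondary IPW hazard ratio from weighted pooled logistic regression.

    Models the discrete-time event odds on a treated-arm indicator plus
    interval-index main effect; the CI uses a patient-clustered sandwich
    variance.  Proportional hazards is not assumed to hold -- the HR is a
    weighted average association reported for comparability only.
    """
    treated, control = arms
    sub = long_df["arm"].isin(arms).to_numpy() & (np.asarray(weights) > 0)
    df = long_df.loc[sub]
    w = np.asarray(weights, dtype=float)[sub]
    y = df["Y"].to_numpy(dtype=float)
    for arm in arms:
        if y[(df["arm"] == arm).to_numpy()].sum() == 0:
            raise EstimatorError(f"no events in arm {arm!r}")

    X = np.column_stack(
        [
            np.ones(len(df)),
            (df["arm"] == treated).to_numpy(dtype=float),
            df["k"].to_numpy(dtype=float),
        ]
    )
    beta = _weighted_logit(X, y, w)
    mu = 1.0 / (1.0 + np.exp(-X @ beta))
    # patient-clustered sandwich
    W = w * mu * (1 - mu)
    bread = np.linalg.inv(X.T @ (X * W[:, None]))
    resid = w * (y - mu)
    score_rows = X * resid[:, None]
    groups = df["patient_id"].to_numpy()
    score_df = pd.DataFrame(score_rows)
    score_df["g"] = groups
    S = score_df.groupby("g").sum().to_numpy()
    meat = S.T @ S
    cov = bread @ meat @ bread
    se = float(np.sqrt(cov[1, 1]))
    log_hr = float(beta[1])
    z = norm.ppf(0.975)
    return float(np.exp(log_hr)), (
        float(np.exp(log_hr - z * se)),
        float(np.exp(log_hr + z * se)),
    )


def _weighted_logit(X, y, w, tol=1e-10, max_iter=100):
    """Newton-Raphson weighted logistic fit (deterministic, no penalty)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (y - mu))
        H = X.T @ (X * (w * mu * (1 - mu))[:, None])
        step = np.linalg.solve(H + 1e-12 * np.eye(len(beta)), grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def effect_modification_test(
    rd1: float, se1: float, rd2: float, se2: float
):
    """Wald test that per-protocol RDs are equal between two disjoint
    subgroups: z = (rd1 - rd2)/sqrt(se1^2 + se2^2), two-sided normal p."""
    if se1 <= 0 and se2 <= 0:
        raise EstimatorError("both subgroup SEs are zero")
    z = (rd1 - rd2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2 * norm.sf(abs(z)))


def contrast_curves(
    curve1: CumulativeIncidenceCurve,
    curve0: CumulativeIncidenceCurve,
    mode: str,
    horizon: int | None = None,
    hr: float | None = None,
    hr_ci: tuple[float, float] | None = None,
) -> ContrastResult:
    """Assemble the full two-arm contrast from a pair of curves."""
    K = _check_aligned(curve1, curve0, horizon)
    rd, rd_se, rd_ci, rd_p = risk_difference(curve1, curve0, K)
    ard, ard_se, ard_ci, ard_p = average_risk_difference(curve1, curve0)
    return ContrastResult(
        arm_treated=curve1.regime.arm,
        arm_control=curve0.regime.arm,
        horizon=K,
        rd=rd, rd_se=rd_se, rd_ci=rd_ci, rd_p=rd_p,
        ard=ard, ard_se=ard_se, ard_ci=ard_ci, ard_p=ard_p,
        nnt=nnt(rd, rd_ci),
        estimator=curve1.estimator,
        mode=mode,
        hr=hr, hr_ci=hr_ci,
    )
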