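"""Counterfactual cumulative incidence estimators.

Three estimators of the per-arm counterfactual cumulative incidence curve
F_a(k) on the 30-day interval grid, all with influence-curve-based SEs:

* ``product_limit_cuminc`` -- weighted discrete-time product-limit.  With
  unit weights this is one minus the Kaplan-Meier survival estimate; with
  cumulative inverse-probability weights it is the IPW estimator of the
  marginal structural (nonparametric) cumulative incidence.
* ``tmle_cuminc`` -- longitudinal targeted minimum loss-based estimation by
  sequential regression (iterated conditional expectation): a backward
  recursion of outcome regressions, each followed by an intercept-only
  logistic fluctuation weighted by the capped cumulative inverse-probability
  product (the clever covariate enters as a weight, which is more stable
  than entering as a regressor under heavy weights).  Doubly robust and
  efficient when both nuisances are consistently estimated.
* ``gcomp_enumerate`` -- exact g-computation over a finite-support discrete
  law; the small-instance oracle used to validate the others.

Non-cardiovascular and unknown-cause deaths are handled as censoring events
(cause-specific risk, not subdistribution risk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.isotonic import IsotonicRegression

from .nuisance import (
    TMLE_CAP,
    NuisanceError,
    NuisanceFit,
    _GlmLearner,
    _LassoLearner,
    _SaturatedLearner,
    cumulative_denominators,
)

_QEPS = 1e-6


class EstimatorError(ValueError):
    """Raised for invalid estimation input."""


@dataclass(frozen=True)
class Regime:
    """A static treatment protocol: which class to initiate, and whether
    sustained exposure (no interruption, no comparator initiation) is
    required (per-protocol) or not (intention-to-treat analog)."""

    arm: str
    sustained: bool = True


@dataclass
class CumulativeIncidenceCurve:
    """Counterfactual risk per interval with influence-curve SEs.

    ``F[k-1]`` is the risk by the end of interval k (k = 1..K); ``ic`` is an
    (n_patients, K) matrix of per-patient influence-curve values, aligned
    with ``patient_ids`` (the full analysis cohort, all arms), so that
    contrasts between arms estimated on the same cohort can difference the
    influence curves patient by patient.
    """

    F: np.ndarray
    se: np.ndarray
    ic: np.ndarray
    patient_ids: np.ndarray
    estimator: str
    regime: Regime
    flags: dict = field(default_factory=dict)

    @property
    def horizon(self) -> int:
        return len(self.F)


def ic_variance(
    ic: np.ndarray,
    n: int | None = None,
    estimate: float | None = None,
    level: float = 0.95,
):
    """Influence-curve SE and Wald CI.

    ``se = sd(ic)/sqrt(n)`` (population sd; the IC is centered by
    construction).  When ``estimate`` is given the CI is
    ``estimate +/- z*se``; otherwise the CI slot is ``None``.
    """
    ic = np.asarray(ic, dtype=float)
    n = len(ic) if n is None else n
    if n < 2:
        raise EstimatorError("need at least 2 influence-curve values")
    se = float(np.std(ic) / np.sqrt(n))
    z = float(norm.ppf(0.5 + level / 2))
    ci = None if estimate is None else (estimate - z * se, estimate + z * se)
    return se, ci


def normal_ci_p(estimate: float, se: float, level: float = 0.95):
    """Wald CI and two-sided normal p-value for an IC-based estimate."""
    z = float(norm.ppf(0.5 + level / 2))
    ci = (estimate - z * se, estimate + z * se)
    p = 1.0 if se == 0 and estimate == 0 else (
        float(2 * norm.sf(abs(estimate) / se)) if se > 0 else 0.0
    )
    return ci, p


# ---------------------------------------------------------------------------
# weighted product-limit
# ---------------------------------------------------------------------------


def unit_weights(long_df: pd.DataFrame, mode: str = "PP") -> np.ndarray:
    """Equal weights of 1 for all at-risk person-time (unadjusted analysis)."""
    w = ((long_df["censor"] == "none") | (long_df["Y"] == 1)).to_numpy(
        dtype=float
    )
    if mode == "PP":
        w *= long_df["adherent"].to_numpy(dtype=float)
    return w


def product_limit_cuminc(
    long_df: pd.DataFrame,
    weights: np.ndarray,
    regime: Regime,
    horizon: int | None = None,
    label: str = "ipw",
) -> CumulativeIncidenceCurve:
    """Weighted discrete-hazard product-limit cumulative incidence.

    The interval hazard is the weighted event fraction among at-risk rows of
    the regime's arm; F(k) = 1 - prod_{j<=k} (1 - hazard_j).  SEs come from
    the delta-method influence-curve expansion over interval hazards,
    treating the weights as known (the conservative convention).
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(long_df):
        raise EstimatorError("weights misaligned with long dataset")
    if (weights < 0).any():
        raise EstimatorError("weights must be non-negative")
    pids = np.unique(long_df["patient_id"].to_numpy())
    n = len(pids)
    pid_idx = {p: i for i, p in enumerate(pids)}
    K = horizon or int(long_df["k"].max()) + 1

    in_arm = (long_df["arm"] == regime.arm).to_numpy()
    rows_i = long_df["patient_id"].map(pid_idx).to_numpy()
    rows_k = long_df["k"].to_numpy()
    WY = np.zeros((n, K))
    WR = np.zeros((n, K))
    sel = in_arm & (rows_k < K) & (weights > 0)
    WY[rows_i[sel], rows_k[sel]] = (
        weights[sel] * long_df["Y"].to_numpy(dtype=float)[sel]
    )
    WR[rows_i[sel], rows_k[sel]] = weights[sel]

    A = WY.mean(axis=0)
    B = WR.mean(axis=0)
    lam = np.zeros(K)
    flags: dict = {}
    for k in range(K):
        if B[k] > 0:
            lam[k] = A[k] / B[k]
        else:
            later = (WR[:, k:] > 0).any() or (WY[:, k:] > 0).any()
            if later:
                flags["truncated_at"] = k
            lam[k:] = 0.0
            break
    surv = np.cumprod(1.0 - lam)
    F = 1.0 - surv

    # IC of F(k): sum_j [S_k/(1-lam_j)] * (w Y - lam_j w R)/B_j
    ic = np.zeros((n, K))
    with np.errstate(divide="ignore", invalid="ignore"):
        per_j = np.where(B > 0, 1.0, 0.0)[None, :] * (
            WY - lam[None, :] * WR
        ) / np.where(B > 0, B, 1.0)[None, :]
    cum = np.zeros(n)
    for k in range(K):
        denom = 1.0 - lam[k]
        contrib = per_j[:, k] / denom if denom > 0 else 0.0
        cum = cum + contrib
        ic[:, k] = surv[k] * cum
    se = ic.std(axis=0) / np.sqrt(n)
    return CumulativeIncidenceCurve(
        F=F, se=se, ic=ic, patient_ids=pids,
        estimator=label, regime=regime, flags=flags,
    )


# ---------------------------------------------------------------------------
# longitudinal TMLE (sequential regression / ICE)
# ---------------------------------------------------------------------------


def _fit_fractional(X, t, method: str, seed: int = 0):
    """Quasi-binomial regression of a [0,1]-valued target.

    Implemented by the two-row expansion (y=1 with weight t, y=0 with weight
    1-t) so penalized logistic learners apply unchanged.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if method == "intercept":
        mean = float(t.mean())
        return lambda Xq: np.full(len(Xq), mean)
    if method in ("saturated", "saturated_history"):
        lr = _SaturatedLearner().fit(
            np.vstack([X, X]),
            np.concatenate([np.ones(len(t)), np.zeros(len(t))]),
            sample_weight=np.concatenate([t, 1.0 - t]),
        )
        return lr.predict_proba_1
    Xe = np.vstack([X, X])
    ye = np.concatenate([np.ones(len(t)), np.zeros(len(t))])
    we = np.concatenate([t, 1.0 - t])
    keep = we > 0
    Xe, ye, we = Xe[keep], ye[keep], we[keep]
    if len(np.unique(ye)) < 2:
        mean = float(ye.mean()) if len(ye) else 0.0
        return lambda Xq: np.full(len(Xq), mean)
    if method == "glm":
        lr = _GlmLearner().fit(Xe, ye, sample_weight=we)
    elif method == "lasso":
        lr = _LassoLearner(seed=seed).fit(Xe, ye, sample_weight=we)
    else:
        raise EstimatorError(f"unknown outcome-regression method {method!r}")
    return lr.predict_proba_1


def _solve_fluctuation(t, q, w):
    """Intercept eps of the weighted logistic fluctuation.

    Solves sum_i w_i (t_i - expit(logit(q_i) + eps)) = 0.  Returns
    (eps, converged).
    """
    if w.sum() == 0 or np.allclose(t, q, atol=1e-14):
        return 0.0, True
    off = logit(np.clip(q, _QEPS, 1 - _QEPS))

    def score(eps):
        return float(np.sum(w * (t - expit(off + eps))))

    lo, hi = -15.0, 15.0
    s_lo, s_hi = score(lo), score(hi)
    if s_lo == 0:
        return lo, True
    if s_hi == 0:
        return hi, True
    if s_lo < 0 or s_hi > 0:  # no sign change: degenerate targets
        return 0.0, False
    return float(brentq(score, lo, hi, xtol=1e-13)), True


def tmle_cuminc(
    long_df: pd.DataFrame,
    fits: dict[str, NuisanceFit],
    regime: Regime,
    horizons: int | list[int],
    q_method: str = "lasso",
    tmle_cap: float = TMLE_CAP,
    seed: int = 0,
) -> CumulativeIncidenceCurve:
    """Longitudinal TMLE of counterfactual cumulative incidence.

    For each requested horizon k*, a backward sequential regression over
    intervals j = k*-1 .. 0: the iterated outcome (event by k*) is regressed
    on current covariates among the regime's at-risk, uncensored (and, for
    sustained regimes, adherent) rows, predicted for everyone still at risk
    under the regime, and targeted by an intercept-only weighted logistic
    fluctuation whose weight is the capped cumulative inverse-probability
    product through j.  F(k*) is the mean targeted baseline prediction over
    the whole cohort; the influence curve is the standard sequential-
    regression sum plus the plug-in residual.

    ``q_method``: 'lasso' (default), 'glm', 'intercept', 'saturated'
    (stratum means of the current row covariates) or 'saturated_history'
    (stratum means of the full covariate history).
    Monotonicity across horizons is enforced by isotonic projection and
    flagged when it binds.
    """
    mode = "PP" if regime.sustained else "ITT"
    denom = cumulative_denominators(long_df, fits, mode)

    pids = np.unique(long_df["patient_id"].to_numpy())
    n = len(pids)
    pid_idx = {p: i for i, p in enumerate(pids)}
    Kmax = int(long_df["k"].max()) + 1
    if isinstance(horizons, int):
        horizons = [horizons]
    horizons = sorted(horizons)
    if max(horizons) > Kmax:
        raise EstimatorError(
            f"horizon {max(horizons)} beyond data horizon {Kmax}"
        )

    lcols = [c for c in long_df.columns if c.startswith(("L_", "M_"))]
    rows_i = long_df["patient_id"].map(pid_idx).to_numpy()
    rows_k = long_df["k"].to_numpy()
    in_arm_row = (long_df["arm"] == regime.arm).to_numpy()

    exists = np.zeros((n, Kmax), dtype=bool)
    uncens = np.zeros((n, Kmax), dtype=bool)
    adher = np.zeros((n, Kmax), dtype=bool)
    Y = np.zeros((n, Kmax))
    D = np.full((n, Kmax), np.nan)
    X = np.full((n, Kmax, len(lcols)), np.nan)
    in_arm = np.zeros(n, dtype=bool)

    exists[rows_i, rows_k] = True
    uncens[rows_i, rows_k] = (long_df["censor"] == "none").to_numpy()
    adher[rows_i, rows_k] = long_df["adherent"].to_numpy(dtype=bool)
    Y[rows_i, rows_k] = long_df["Y"].to_numpy(dtype=float)
    D[rows_i, rows_k] = denom
    X[rows_i, rows_k, :] = long_df[lcols].to_numpy(dtype=float)
    in_arm[rows_i[in_arm_row]] = True

    follow = uncens | (Y == 1)  # observation of the interval's outcome
    if regime.sustained:
        follow &= adher

    F_out = np.zeros(len(horizons))
    se_out = np.zeros(len(horizons))
    ic_out = np.zeros((n, len(horizons)))
    flags: dict = {"untargeted_steps": []}

    for hi, kstar in enumerate(horizons):
        ic = np.zeros(n)
        q_next = np.zeros(n)  # targeted Q at step j+1, valid on pred set
        for j in range(kstar - 1, -1, -1):
            fit_set = in_arm & exists[:, j] & follow[:, j]
            pred_set = (
                (in_arm & exists[:, j]) if j > 0 else np.ones(n, dtype=bool)
            )
            if j == kstar - 1:
                target = Y[:, j]
            else:
                target = np.where(Y[:, j] == 1, 1.0, q_next)

            t_fit = target[fit_set]
            w_fit = np.minimum(1.0 / D[fit_set, j], tmle_cap)
            if fit_set.sum() == 0:
                q_pred = np.zeros(n)
                q_star = q_pred
                flags["untargeted_steps"].append((kstar, j))
            else:
                if q_method == "saturated_history":
                    Xj_all = _history_design(X, exists, j)
                else:
                    Xj_all = X[:, j, :]
                    if j == 0:
                        # everyone has a baseline row; use it for prediction
                        Xj_all = np.where(
                            np.isnan(Xj_all), 0.0, Xj_all
                        )
                if np.all(t_fit == t_fit[0]):
                    # deterministic target; no regression or targeting needed
                    q_star = np.full(n, float(t_fit[0]))
                else:
                    predict = _fit_fractional(
                        Xj_all[fit_set], t_fit, q_method, seed=seed
                    )
                    q_pred = np.zeros(n)
                    q_pred[pred_set] = np.clip(
                        predict(Xj_all[pred_set]), _QEPS, 1 - _QEPS
                    )
                    eps, ok = _solve_fluctuation(
                        t_fit, q_pred[fit_set], w_fit
                    )
                    if not ok:
                        flags["untargeted_steps"].append((kstar, j))
                        warnings.warn(
                            f"TMLE fluctuation degenerate at horizon {kstar},"
                            f" step {j}; using untargeted fit",
                            stacklevel=2,
                        )
                    q_star = np.zeros(n)
                    q_star[pred_set] = expit(
                        logit(np.clip(q_pred[pred_set], _QEPS, 1 - _QEPS))
                        + eps
                    )
            ic[fit_set] += w_fit * (t_fit - q_star[fit_set])
            q_next = q_star
        Fk = float(q_next.mean())  # pred set at j=0 is everyone
        ic += q_next - Fk
        F_out[hi] = Fk
        se_out[hi], _ = ic_variance(ic)
        ic_out[:, hi] = ic

    if len(horizons) > 1 and np.any(np.diff(F_out) < 0):
        iso = IsotonicRegression(increasing=True)
        F_out = iso.fit_transform(np.arange(len(F_out)), F_out)
        flags["isotonic_projection"] = True
    if not flags["untargeted_steps"]:
        del flags["untargeted_steps"]
    return CumulativeIncidenceCurve(
        F=F_out, se=se_out, ic=ic_out, patient_ids=pids,
        estimator="tmle", regime=regime, flags=flags,
    )


def _history_design(X, exists, j):
    """Design matrix of the concatenated covariate history through row j.

    Patients without a row at some step get NaN-free zeros there (they are
    never in the fitting or prediction sets that use those entries)."""
    parts = [np.nan_to_num(X[:, jj, :], nan=0.0) for jj in range(j + 1)]
    return np.hstack(parts)


# ---------------------------------------------------------------------------
# exact g-computation on a finite discrete law
# ---------------------------------------------------------------------------

MAX_SUPPORT = 100_000


@dataclass
class DiscreteLaw:
    """Finite-support longitudinal law for exact enumeration.

    ``l0`` maps baseline covariate tuples to probabilities.  ``hazard`` maps
    ``(arm, k, history)`` -- history being the tuple of covariate tuples
    observed through interval k -- to the event probability in interval k.
    ``transition`` maps ``(arm, k, history)`` to the distribution of the
    next interval's covariate tuple.  Missing transition entries mean the
    covariates stay frozen; missing hazard entries mean hazard 0.
    """

    l0: dict[tuple, float]
    hazard: dict[tuple, float]
    transition: dict[tuple, dict[tuple, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.l0.values())
        if abs(total - 1.0) > 1e-9:
            raise EstimatorError(f"baseline law sums to {total}, not 1")


def gcomp_enumerate(
    law: DiscreteLaw, regime: Regime, horizon: int
) -> np.ndarray:
    """Exact counterfactual cumulative incidence by history enumeration."""
    arm = regime.arm
    F = np.zeros(horizon)
    # frontier: history -> probability of that history with no event yet
    frontier: dict[tuple, float] = {
        (l0,): p for l0, p in law.l0.items() if p > 0
    }
    cum_risk = 0.0
    for k in range(horizon):
        if len(frontier) > MAX_SUPPORT:
            raise EstimatorError(
                f"history support exceeds {MAX_SUPPORT} at interval {k}"
            )
        new_frontier: dict[tuple, float] = {}
        for hist, prob in frontier.items():
            lam = law.hazard.get((arm, k, hist), 0.0)
            cum_risk += prob * lam
            surv_mass = prob * (1.0 - lam)
            if surv_mass <= 0 or k == horizon - 1:
                continue
            trans = law.transition.get((arm, k, hist))
            if trans is None:
                nxt = hist + (hist[-1],)
                new_frontier[nxt] = new_frontier.get(nxt, 0.0) + surv_mass
            else:
                for nxt_val, tp in trans.items():
                    if tp <= 0:
                        continue
                    nxt = hist + (nxt_val,)
                    new_frontier[nxt] = (
                        new_frontier.get(nxt, 0.0) + surv_mass * tp
                    )
        F[k] = cum_risk
        frontier = new_frontier
    return F


def empirical_discrete_law(
    long_df: pd.DataFrame, covariate_cols: list[str] | None = None
) -> DiscreteLaw:
    """The empirical distribution of a (small, discrete) long dataset.

    Builds baseline, hazard and transition tables by empirical frequencies
    conditioned on the full covariate history within each arm; used as the
    reference law for saturated-equivalence checks.
    """
    if covariate_cols is None:
        covariate_cols = [c for c in long_df.columns if c.startswith("L_")]
    wide = {}
    for pid, grp in long_df.groupby("patient_id"):
        grp = grp.sort_values("k")
        wide[pid] = (
            str(grp["arm"].iloc[0]),
            [tuple(r) for r in grp[covariate_cols].to_numpy()],
            grp["Y"].to_numpy(),
        )
    n = len(wide)
    l0_counts: dict[tuple, float] = {}
    haz_counts: dict[tuple, list[float]] = {}
    trans_counts: dict[tuple, dict[tuple, float]] = {}
    for arm, covs, y in wide.values():
        l0_counts[covs[0]] = l0_counts.get(covs[0], 0.0) + 1.0
        hist: tuple = ()
        for k, (cv, yk) in enumerate(zip(covs, y)):
            hist = hist + (cv,)
            acc = haz_counts.setdefault((arm, k, hist), [0.0, 0.0])
            acc[0] += yk
            acc[1] += 1.0
            if yk == 0 and k + 1 < len(covs):
                tdist = trans_counts.setdefault((arm, k, hist), {})
                nxt = covs[k + 1]
                tdist[nxt] = tdist.get(nxt, 0.0) + 1.0
    l0 = {key: cnt / n for key, cnt in l0_counts.items()}
    hazard = {
        key: num / den for key, (num, den) in haz_counts.items() if den > 0
    }
    transition = {}
    for key, dist in trans_counts.items():
        tot = sum(dist.values())
        transition[key] = {nxt: cnt / tot for nxt, cnt in dist.items()}
    return DiscreteLaw(l0=l0, hazard=hazard, transition=transition)
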