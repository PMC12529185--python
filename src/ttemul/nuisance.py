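"""Nuisance models: super-learner propensities and inverse-probability weights.

Propensity scores for treatment initiation, treatment continuation (no
interruption or crossover) and each right-censoring cause are fitted at
each time point separately via a cross-validated stacking ensemble (super
learner): candidate learners are fit on V folds, and a convex combination
of their held-out predictions minimizing the cross-validated negative
Bernoulli log-likelihood forms the ensemble, falling back to the best
single learner when the convex fit is degenerate.  Intervals with too few
events fall back to a single fit pooled over time with the interval index
as a predictor.  Predictions are bounded away from 0 and 1, and cumulative
inverse-probability weights support percentile and absolute truncation
(defaults 99th percentile / cap 20 for IPW; cap 200 for the TMLE targeting
weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

G_FLOOR = 0.005
PROB_EPS = 1e-12


class NuisanceError(ValueError):
    """Raised for invalid nuisance-model input."""


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------


class _InterceptLearner:
    """Predicts the (weighted) outcome mean regardless of covariates."""

    def fit(self, X, y, sample_weight=None):
        self.p_ = float(np.average(y, weights=sample_weight))
        return self

    def predict_proba_1(self, X):
        return np.full(len(X), self.p_)


class _GlmLearner:
    """Main-terms logistic regression (unpenalized)."""

    def fit(self, X, y, sample_weight=None):
        if len(np.unique(y)) < 2:
            self.const_ = float(np.mean(y))
            return self
        self.const_ = None
        self.model_ = LogisticRegression(
            C=np.inf, max_iter=2000, solver="lbfgs"
        ).fit(X, y, sample_weight=sample_weight)
        return self

    def predict_proba_1(self, X):
        if self.const_ is not None:
            return np.full(len(X), self.const_)
        return self.model_.predict_proba(X)[:, 1]


class _LassoLearner:
    """L1-penalized logistic regression, penalty chosen by small-grid CV."""

    def __init__(self, seed: int = 0, Cs=(0.01, 0.1, 1.0, 10.0), cv: int = 3):
        self.seed, self.Cs, self.cv = seed, Cs, cv

    def fit(self, X, y, sample_weight=None):
        if len(np.unique(y)) < 2:
            self.const_ = float(np.mean(y))
            return self
        self.const_ = None
        best, best_loss = None, np.inf
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        folds = StratifiedKFold(
            n_splits=min(self.cv, int(np.bincount(y.astype(int)).min())),
            shuffle=True,
            random_state=self.seed,
        ) if np.bincount(y.astype(int)).min() >= 2 else None
        for C in self.Cs:
            if folds is None:
                loss = 0.0
            else:
                loss = 0.0
                for tr, te in folds.split(X, y):
                    if len(np.unique(y[tr])) < 2:
                        continue
                    m = LogisticRegression(
                        l1_ratio=1.0, C=C, solver="liblinear",
                        random_state=self.seed,
                    ).fit(
                        X[tr], y[tr],
                        sample_weight=None if sample_weight is None
                        else sample_weight[tr],
                    )
                    p = np.clip(
                        m.predict_proba(X[te])[:, 1], PROB_EPS, 1 - PROB_EPS
                    )
                    w = (
                        np.ones(len(te)) if sample_weight is None
                        else sample_weight[te]
                    )
                    loss += -np.sum(
                        w * (y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
                    )
            if loss < best_loss:
                best_loss, best = loss, C
        self.model_ = LogisticRegression(
            l1_ratio=1.0, C=best, solver="liblinear", random_state=self.seed
        ).fit(X, y, sample_weight=sample_weight)
        return self

    def predict_proba_1(self, X):
        if self.const_ is not None:
            return np.full(len(X), self.const_)
        return self.model_.predict_proba(np.asarray(X, dtype=float))[:, 1]


class _SaturatedLearner:
    """Empirical stratum means over the discrete covariate pattern.

    Nonparametric: each distinct covariate row is its own stratum; unseen
    strata fall back to the overall mean.  Only sensible for a handful of
    discrete covariates.
    """

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.ones(len(y)) if sample_weight is None else sample_weight
        self.table_ = {}
        sums: dict[tuple, list[float]] = {}
        for row, yi, wi in zip(map(tuple, X), y, w):
            acc = sums.setdefault(row, [0.0, 0.0])
            acc[0] += wi * yi
            acc[1] += wi
        self.table_ = {
            key: num / den for key, (num, den) in sums.items() if den > 0
        }
        self.overall_ = float(np.average(y, weights=w))
        return self

    def predict_proba_1(self, X):
        X = np.asarray(X, dtype=float)
        return np.array(
            [self.table_.get(tuple(row), self.overall_) for row in X]
        )


_LEARNER_FACTORIES = {
    "intercept": lambda seed: _InterceptLearner(),
    "glm": lambda seed: _GlmLearner(),
    "lasso": lambda seed: _LassoLearner(seed=seed),
    "saturated": lambda seed: _SaturatedLearner(),
}


def make_learner(spec, seed: int = 0):
    """Instantiate a learner from a name or a (name, factory) pair."""
    if isinstance(spec, str):
        try:
            return _LEARNER_FACTORIES[spec](seed)
        except KeyError:
            raise NuisanceError(f"unknown learner {spec!r}") from None
    name, factory = spec
    return factory(seed)


@dataclass
class LearnerLibrary:
    """Ordered candidate learners plus the CV scheme for stacking."""

    learners: Sequence = ("intercept", "glm", "lasso")
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.learners) < 1:
            raise NuisanceError("library needs at least one learner")
        if self.cv_folds < 2:
            raise NuisanceError("cv_folds must be >= 2")

    def names(self) -> list[str]:
        return [
            spec if isinstance(spec, str) else spec[0]
            for spec in self.learners
        ]


# ---------------------------------------------------------------------------
# super learner
# ---------------------------------------------------------------------------


def _log_loss(y, p, eps=PROB_EPS):
    p = np.clip(p, eps, 1 - eps)
    return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))


@dataclass
class SuperLearnerFit:
    """A fitted stacking ensemble over a learner library."""

    learners: list
    names: list[str]
    weights: np.ndarray
    cv_losses: np.ndarray
    degenerate: bool = False
    constant: float | None = None

    def predict_proba_1(self, X) -> np.ndarray:
        if self.constant is not None:
            return np.full(len(X), self.constant)
        preds = np.column_stack(
            [lr.predict_proba_1(X) for lr in self.learners]
        )
        return preds @ self.weights


def fit_super_learner(
    X, y, library: LearnerLibrary | None = None
) -> SuperLearnerFit:
    """Cross-validated convex-stacking ensemble for a binary target.

    Per-learner held-out predictions are combined with simplex weights
    minimizing the CV negative log-likelihood; a degenerate convex fit
    falls back to the discrete super learner (best single learner).
    A constant target yields a constant predictor with a warning flag
    rather than an error (a censoring cause may simply be absent).
    """
    library = library or LearnerLibrary()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = library.names()
    if len(np.unique(y)) < 2:
        warnings.warn(
            "constant target: returning constant predictor", stacklevel=2
        )
        return SuperLearnerFit(
            learners=[], names=names, weights=np.array([]),
            cv_losses=np.array([]), degenerate=True, constant=float(y.mean()),
        )

    n_minority = int(np.bincount(y.astype(int)).min())
    folds = min(library.cv_folds, max(2, n_minority))
    splitter = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=library.seed
    )
    cv_pred = np.zeros((len(y), len(names)))
    for tr, te in splitter.split(X, y):
        for j, spec in enumerate(library.learners):
            lr = make_learner(spec, seed=library.seed)
            lr.fit(X[tr], y[tr])
            cv_pred[te, j] = lr.predict_proba_1(X[te])

    cv_losses = np.array(
        [_log_loss(y, cv_pred[:, j]) for j in range(len(names))]
    )
    best_single = int(np.argmin(cv_losses))

    if len(names) == 1:
        weights, degenerate = np.array([1.0]), False
    else:
        def objective(w):
            return _log_loss(y, cv_pred @ w)

        w0 = np.full(len(names), 1.0 / len(names))
        res = minimize(
            objective, w0, method="SLSQP",
            bounds=[(0.0, 1.0)] * len(names),
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        weights = np.clip(res.x, 0.0, None)
        weights = weights / weights.sum() if weights.sum() > 0 else w0
        degenerate = not res.success
        # guarantee CV-loss dominance over every single learner
        if (
            degenerate
            or _log_loss(y, cv_pred @ weights) > cv_losses[best_single] + 1e-10
        ):
            weights = np.zeros(len(names))
            weights[best_single] = 1.0
            degenerate = True

    learners = []
    for spec in library.learners:
        lr = make_learner(spec, seed=library.seed)
        lr.fit(X, y)
        learners.append(lr)
    return SuperLearnerFit(
        learners=learners, names=names, weights=weights,
        cv_losses=cv_losses, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# propensity series
# ---------------------------------------------------------------------------

KNOWN_KINDS = (
    "initiation",
    "continuation",
    "censor:disenrollment",
    "censor:noncv_death",
    "censor:unknown_death",
)

_TARGETS = {
    "continuation": lambda df: (df["censor"] == "artificial_pp"),
    "censor:disenrollment": lambda df: (df["censor"] == "disenrollment"),
    "censor:noncv_death": lambda df: (df["censor"] == "noncv_death"),
    "censor:unknown_death": lambda df: (df["censor"] == "unknown_death"),
}

# Within-interval claiming order for sequential conditioning: each cause is
# fitted among rows not already claimed by an earlier cause, so the product
# of fitted complements is the probability of remaining at risk.
_CLAIM_ORDER = (
    "artificial_pp",
    "noncv_death",
    "unknown_death",
    "disenrollment",
)

_KIND_CAUSE = {
    "continuation": "artificial_pp",
    "censor:disenrollment": "disenrollment",
    "censor:noncv_death": "noncv_death",
    "censor:unknown_death": "unknown_death",
}


def predictor_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(("L_", "M_"))]


def _design(df: pd.DataFrame, cols, with_k=False, with_arm=None):
    parts = [df[cols].to_numpy(dtype=float)]
    if with_k:
        parts.append(df[["k"]].to_numpy(dtype=float))
    if with_arm is not None:
        arms = sorted(with_arm)
        for arm in arms[1:]:
            parts.append((df["arm"] == arm).to_numpy(dtype=float)[:, None])
    return np.hstack(parts)


@dataclass
class NuisanceFit:
    """Per-interval (or pooled) fitted predictors for one nuisance kind.

    ``predict(df)`` returns the fitted probability of the modelled event
    (initiating a given arm; deviating; being censored by the given cause)
    for every row, bounded to ``[g_floor, 1 - g_floor]``.
    """

    kind: str
    per_interval: dict[int, SuperLearnerFit] = field(default_factory=dict)
    pooled: SuperLearnerFit | None = None
    arm: str | None = None  # initiation fits are per arm
    arms: tuple[str, ...] = ()
    g_floor: float = G_FLOOR
    predictors: list[str] = field(default_factory=list)

    def _bound(self, p: np.ndarray) -> np.ndarray:
        # The floor guards the quantities that enter weight denominators:
        # the initiation propensity itself, and the remain-uncensored factor
        # 1 - p for censoring/continuation fits (so an absent cause yields a
        # factor of exactly 1, not 1 - floor).
        if self.kind == "initiation":
            return np.clip(p, self.g_floor, 1.0 - self.g_floor)
        return np.clip(p, 0.0, 1.0 - self.g_floor)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(df))
        with_arm = self.arms if self.kind != "initiation" else None
        if self.kind == "initiation":
            X_all = _design(df, self.predictors)
        else:
            X_all = _design(df, self.predictors, with_k=True, with_arm=with_arm)
        ks = df["k"].to_numpy()
        done = np.zeros(len(df), dtype=bool)
        for k, fit in self.per_interval.items():
            mask = ks == k
            if mask.any():
                out[mask] = fit.predict_proba_1(X_all[mask])
                done |= mask
        if not done.all():
            if self.pooled is None:
                missing = sorted(set(ks[~done]))
                raise NuisanceError(
                    f"{self.kind}: no fit for intervals {missing} and no "
                    "pooled fallback"
                )
            out[~done] = self.pooled.predict_proba_1(X_all[~done])
        return self._bound(out)


def fit_propensity_series(
    long_df: pd.DataFrame,
    kind: str,
    library: LearnerLibrary | None = None,
    pooling: str = "auto",
    min_events: int = 25,
    g_floor: float = G_FLOOR,
    arm: str | None = None,
) -> NuisanceFit:
    """Fit one nuisance kind at each time point separately.

    ``kind`` is ``initiation`` (requires ``arm``: models P(assigned arm |
    baseline covariates) on interval-0 rows), ``continuation`` (probability
    of a protocol deviation this interval, PP rows), or ``censor:<cause>``.
    Intervals with fewer than ``min_events`` modelled events fall back to a
    pooled-over-time fit with the interval index as predictor
    (``pooling='pooled_with_time'`` forces the pooled fit everywhere).
    """
    library = library or LearnerLibrary()
    if kind not in KNOWN_KINDS:
        raise NuisanceError(f"unknown nuisance kind {kind!r}")
    cols = predictor_columns(long_df)
    arms = tuple(sorted(long_df["arm"].unique()))
    fit = NuisanceFit(
        kind=kind, arm=arm, arms=arms, g_floor=g_floor, predictors=cols
    )

    if kind == "initiation":
        if arm is None:
            raise NuisanceError("initiation fit requires the arm to model")
        base = long_df[long_df["k"] == 0]
        y = (base["arm"] == arm).to_numpy(dtype=float)
        X = _design(base, cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit.per_interval[0] = fit_super_learner(X, y, library)
            fit.pooled = fit.per_interval[0]
        return fit

    cause = _KIND_CAUSE[kind]
    earlier = _CLAIM_ORDER[: _CLAIM_ORDER.index(cause)]
    sub = long_df[~long_df["censor"].isin(earlier)]
    target = _TARGETS[kind](sub).to_numpy(dtype=float)
    X = _design(sub, cols, with_k=True, with_arm=arms)
    ks = sub["k"].to_numpy()

    sparse_ks = []
    if pooling != "pooled_with_time":
        for k in sorted(np.unique(ks)):
            mask = ks == k
            if target[mask].sum() >= min_events:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit.per_interval[int(k)] = fit_super_learner(
                        X[mask], target[mask], library
                    )
            else:
                sparse_ks.append(int(k))
    if pooling == "pooled_with_time" or sparse_ks:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit.pooled = fit_super_learner(X, target, library)
    return fit


# ---------------------------------------------------------------------------
# cumulative weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncationSpec:
    """How to truncate cumulative inverse-probability weights."""

    style: str = "absolute"
    percentile: float = 99.0
    absolute_cap: float = 20.0

    def __post_init__(self) -> None:
        if self.style not in ("none", "percentile", "absolute"):
            raise NuisanceError(f"unknown truncation style {self.style!r}")
        if not 50.0 < self.percentile <= 100.0:
            raise NuisanceError("percentile must lie in (50, 100]")
        if self.absolute_cap <= 1.0:
            raise NuisanceError("absolute_cap must exceed 1")


IPW_TRUNCATION = TruncationSpec(style="absolute", absolute_cap=20.0)
TMLE_CAP = 200.0


def apply_truncation(
    weights: np.ndarray, spec: TruncationSpec
) -> tuple[np.ndarray, dict]:
    """Truncate final cumulative weights; reports the fraction altered."""
    w = np.asarray(weights, dtype=float).copy()
    pos = w > 0
    if spec.style == "none" or not pos.any():
        return w, {"style": spec.style, "fraction_altered": 0.0, "cap": None}
    if spec.style == "percentile":
        cap = float(np.percentile(w[pos], spec.percentile))
    else:
        cap = float(spec.absolute_cap)
    altered = (w > cap).sum() / pos.sum()
    w = np.minimum(w, cap)
    return w, {
        "style": spec.style, "fraction_altered": float(altered), "cap": cap,
    }


def cumulative_denominators(
    long_df: pd.DataFrame,
    fits: dict[str, NuisanceFit],
    mode: str,
) -> np.ndarray:
    """Per-row cumulative probability product g_0:k (no indicators applied).

    The row-k denominator is g_init(own arm | L_0) times the product over
    intervals j <= k of the fitted probabilities of remaining uncensored by
    every modelled cause (and, in PP mode, of not deviating).
    """
    needed = ["initiation:" + arm for arm in sorted(long_df["arm"].unique())]
    for key in needed:
        if key not in fits:
            raise NuisanceError(f"missing nuisance fit {key!r}")
    if mode == "PP" and "continuation" not in fits:
        raise NuisanceError("missing nuisance fit 'continuation' (PP mode)")

    n = len(long_df)
    log_factor = np.zeros(n)
    for key, fit in fits.items():
        if key.startswith("initiation:"):
            continue
        if fit.kind == "continuation" and mode != "PP":
            continue
        p_event = fit.predict(long_df)
        log_factor += np.log1p(-p_event)

    base = long_df[long_df["k"] == 0]
    g_init_row = np.zeros(len(base))
    for arm in sorted(long_df["arm"].unique()):
        mask = (base["arm"] == arm).to_numpy()
        g_init_row[mask] = fits["initiation:" + arm].predict(base)[mask]
    g_init = pd.Series(g_init_row, index=base["patient_id"].to_numpy())

    df = long_df[["patient_id"]].copy()
    df["log_factor"] = log_factor
    cum = df.groupby("patient_id", sort=False)["log_factor"].cumsum()
    denom = np.exp(cum.to_numpy()) * g_init.reindex(
        long_df["patient_id"]
    ).to_numpy()
    return denom


def cumulative_weights(
    long_df: pd.DataFrame,
    fits: dict[str, NuisanceFit],
    mode: str = "PP",
    truncation: TruncationSpec | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-row cumulative inverse-probability weights.

    Rows that are censored or (in PP mode) non-adherent get weight 0; all
    other rows get the inverse of the cumulative denominator through their
    interval.  Truncation (default absolute cap 20) applies to the final
    cumulative weight.
    """
    truncation = truncation if truncation is not None else IPW_TRUNCATION
    denom = cumulative_denominators(long_df, fits, mode)
    at_risk = (long_df["censor"] == "none").to_numpy() | (
        long_df["Y"] == 1
    ).to_numpy()
    if mode == "PP":
        at_risk &= long_df["adherent"].to_numpy(dtype=bool)
    raw = np.where(at_risk, 1.0 / denom, 0.0)
    w, info = apply_truncation(raw, truncation)
    info["mean_weight"] = float(w[at_risk].mean()) if at_risk.any() else 0.0
    return w, info
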