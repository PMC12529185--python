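"""Robustness analyses: truncation sweeps, outcome variants, g-values.

The g-value quantifies robustness to unmeasured confounding and selection
bias on the risk-difference scale: the smallest additive bias that, applied
toward the null, would make the 95% CI include 0.  A conclusion with a
large g-value relative to its estimate needs a large hidden bias to be
overturned; a g-value of 0 means the estimate is already nonsignificant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contrasts import risk_difference
from .estimators import EstimatorError, Regime, product_limit_cuminc, tmle_cuminc
from .nuisance import TruncationSpec, cumulative_weights
from .persontime import OutcomeDefinition
from .pipeline import EmulationConfig, PipelineState, run_emulation
from .simulate import EVENT_TYPES


@dataclass
class GValue:
    delta: float
    fraction_of_estimate: float
    direction: str  # 'strengthen' if bias must exceed delta to nullify


def g_value(estimate: float, se: float | None = None, ic=None) -> GValue:
    """Additive bias needed to nullify significance: max(0, |est| - 1.96 se).

    Accepts either the IC-based SE directly or the influence-curve values.
    """
    if se is None:
        if ic is None:
            raise EstimatorError("need se or influence-curve values")
        ic = np.asarray(ic, dtype=float)
        se = float(np.std(ic) / np.sqrt(len(ic)))
    if se <= 0:
        raise EstimatorError("se must be positive")
    delta = max(0.0, abs(estimate) - 1.96 * se)
    frac = delta / abs(estimate) if estimate != 0 else 0.0
    return GValue(
        delta=delta,
        fraction_of_estimate=frac,
        direction="strengthen" if delta > 0 else "already_null",
    )


def truncation_sweep(
    state: PipelineState, specs: list[TruncationSpec], estimator: str = "ipw"
) -> pd.DataFrame:
    """Re-estimate the arm contrast under each truncation spec.

    Reuses the fitted nuisance models -- only the weight truncation (and
    for TMLE the targeting-weight cap) changes.
    """
    rows = []
    for spec in specs:
        weights, info = cumulative_weights(
            state.long_df, state.fits, mode=state.mode, truncation=spec
        )
        sustained = state.mode == "PP"
        if estimator == "tmle":
            cap = (
                spec.absolute_cap if spec.style == "absolute" else
                state.tmle_cap
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c1 = tmle_cuminc(
                    state.long_df, state.fits,
                    Regime(state.treated, sustained), [state.horizon],
                    q_method=state.q_method, tmle_cap=cap, seed=state.seed,
                )
                c0 = tmle_cuminc(
                    state.long_df, state.fits,
                    Regime(state.control, sustained), [state.horizon],
                    q_method=state.q_method, tmle_cap=cap, seed=state.seed,
                )
        else:
            c1 = product_limit_cuminc(
                state.long_df, weights, Regime(state.treated, sustained),
                horizon=state.horizon,
            )
            c0 = product_limit_cuminc(
                state.long_df, weights, Regime(state.control, sustained),
                horizon=state.horizon,
            )
        rd, se, ci, p = risk_difference(c1, c0)
        rows.append(
            {
                "style": spec.style,
                "cap": info["cap"],
                "fraction_altered": info["fraction_altered"],
                "max_weight": float(weights.max()),
                "rd": rd,
                "rd_se": se,
                "rd_lcl": ci[0],
                "rd_ucl": ci[1],
                "rd_p": p,
            }
        )
    return pd.DataFrame(rows)


def outcome_variant(
    config: EmulationConfig,
    alternative: OutcomeDefinition,
    tables=None,
):
    """Re-run the full emulation under an alternative composite outcome.

    Returns ``(primary_report, variant_report)`` for side-by-side
    comparison.  The alternative must match at least one event type or
    death cause that can occur in the data.
    """
    known_events = set(EVENT_TYPES)
    known_deaths = {"cardiovascular", "noncardiovascular", "unknown"}
    if not (
        set(alternative.event_types) & known_events
        or set(alternative.death_causes) & known_deaths
    ):
        raise EstimatorError(
            "alternative outcome definition matches no event type or death"
            " cause present in the data"
        )
    primary = run_emulation(config, tables=tables)
    variant_config = replace(config, outcome=alternative)
    variant = run_emulation(variant_config, tables=tables)
    return primary, variant
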