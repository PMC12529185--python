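"""Scenario configuration for the synthetic EHR world.

A :class:`ScenarioConfig` fully specifies a data-generating world: baseline
covariates, confounded treatment initiation, first-order-Markov time-varying
covariate dynamics, per-interval discontinuation/crossover, per-cause
informative censoring, a discrete-time event hazard driven by the
dispensing-derived exposure state, and the dispensing process itself
(days'-supply and refill-delay distributions).  All model components are
logistic/linear with named coefficients, so validation scenarios can make
analysis models exactly correct or deliberately wrong.

Time is integer days from a scenario-wide origin (day 0); decision intervals
are 30 days, half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

INTERVAL_DAYS = 30

#: Medication-class labels used by the bundled scenarios (sulfonylurea,
#: DPP-4 inhibitor, SGLT2 inhibitor, GLP-1 receptor agonist).
ALL_CLASSES = ("su", "dpp4i", "sglt2i", "glp1ra")


class ConfigError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: name, kind and sampling parameters.

    Binary covariates take ``params={"p": ...}``; continuous covariates take
    ``params={"mean": ..., "sd": ...}``.
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ConfigError(
                f"covariate {self.name!r}: kind must be binary or continuous"
            )
        if self.kind == "binary" and not 0 < self.params.get("p", -1) < 1:
            raise ConfigError(f"covariate {self.name!r}: need 0 < p < 1")
        if self.kind == "continuous" and self.params.get("sd", -1) <= 0:
            raise ConfigError(f"covariate {self.name!r}: need sd > 0")


@dataclass(frozen=True)
class DispensingSpec:
    """Days'-supply and refill-delay distributions.

    The next refill is scheduled ``days_supply + delay`` days after a fill,
    with ``delay`` uniform on ``[refill_delay_min, refill_delay_max]``.
    Because coverage lasts twice the supply, the inter-coverage gap is
    ``delay - supply`` and must stay within the allowable 90-day gap for
    refill behaviour to keep exposure unbroken.
    """

    supplies: tuple[int, ...] = (30, 60, 90)
    supply_probs: tuple[float, ...] = (0.6, 0.3, 0.1)
    refill_delay_min: int = 0
    refill_delay_max: int = 45

    def __post_init__(self) -> None:
        if len(self.supplies) != len(self.supply_probs):
            raise ConfigError("supplies and supply_probs differ in length")
        if abs(sum(self.supply_probs) - 1.0) > 1e-9:
            raise ConfigError("supply_probs must sum to 1")
        if min(self.supplies) < 1:
            raise ConfigError("days' supply must be >= 1")
        if not 0 <= self.refill_delay_min <= self.refill_delay_max:
            raise ConfigError(
                "need 0 <= refill_delay_min <= refill_delay_max"
            )
        if self.refill_delay_max - min(self.supplies) > 90:
            raise ConfigError(
                "refill_delay_max would allow gaps beyond the 90-day limit"
            )


# Coefficient dicts map covariate names to coefficients, plus the reserved
# keys 'intercept', 'prev' (dynamics only) and 'exposure' (a per-class dict).
RESERVED_KEYS = {"intercept", "prev", "exposure", "kind", "sd"}


@dataclass
class ScenarioConfig:
    n_patients: int
    baseline_covariates: list[CovariateSpec]
    treatment_model: dict[str, dict[str, float]]
    hazard_model: dict[str, object]
    med_classes: tuple[str, ...] = ("su", "glp1ra")
    horizon_days: int = 900
    covariate_dynamics: dict[str, dict] = field(default_factory=dict)
    continuation_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "discontinue": {"intercept": -30.0},
            "crossover": {"intercept": -30.0},
        }
    )
    censoring_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "disenrollment": {"intercept": -30.0},
            "noncv_death": {"intercept": -30.0},
        }
    )
    unknown_death_frac: float = 0.05
    event_type_probs: dict[str, float] = field(
        default_factory=lambda: {"MI": 0.45, "CVA": 0.35, "cv_death": 0.20}
    )
    missingness_rate: float = 0.1
    dual_initiation_rate: float = 0.0
    dispensing_spec: DispensingSpec = field(default_factory=DispensingSpec)
    seed: int = 0

    # -- derived ----------------------------------------------------------
    @property
    def n_classes(self) -> int:
        return len(self.med_classes)

    @property
    def n_intervals(self) -> int:
        return self.horizon_days // INTERVAL_DAYS

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.baseline_covariates]

    @property
    def time_varying_names(self) -> list[str]:
        return [
            c.name for c in self.baseline_covariates
            if c.name in self.covariate_dynamics
        ]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        if self.n_classes not in (2, 4):
            raise ConfigError(
                f"med_classes must have 2 or 4 entries, got {self.med_classes}"
            )
        if self.horizon_days <= 0 or self.horizon_days % INTERVAL_DAYS:
            raise ConfigError(
                f"horizon_days must be a positive multiple of {INTERVAL_DAYS},"
                f" got {self.horizon_days}"
            )
        if not 0 <= self.missingness_rate <= 1:
            raise ConfigError("missingness_rate must lie in [0, 1]")
        if not 0 <= self.unknown_death_frac <= 1:
            raise ConfigError("unknown_death_frac must lie in [0, 1]")
        if not 0 <= self.dual_initiation_rate < 1:
            raise ConfigError("dual_initiation_rate must lie in [0, 1)")
        if abs(sum(self.event_type_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("event_type_probs must sum to 1")
        known = set(self.covariate_names)
        for med in self.treatment_model:
            if med not in self.med_classes:
                raise ConfigError(f"treatment_model: unknown class {med!r}")
        for label, coefs in self._all_coef_dicts():
            for key in coefs:
                if key in RESERVED_KEYS:
                    continue
                if key not in known:
                    raise ConfigError(
                        f"{label}: coefficient on unknown covariate {key!r}"
                    )
        for name in self.covariate_dynamics:
            if name not in known:
                raise ConfigError(
                    f"covariate_dynamics for unknown covariate {name!r}"
                )

    def _all_coef_dicts(self):
        for med, coefs in self.treatment_model.items():
            yield f"treatment_model[{med}]", coefs
        yield "hazard_model", {
            k: v for k, v in self.hazard_model.items() if k != "exposure"
        }
        for name, coefs in self.continuation_model.items():
            yield f"continuation_model[{name}]", coefs
        for name, coefs in self.censoring_model.items():
            yield f"censoring_model[{name}]", coefs
        for name, dyn in self.covariate_dynamics.items():
            yield f"covariate_dynamics[{name}]", {
                k: v for k, v in dyn.items() if k not in ("exposure",)
            }

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_covariates"] = [
            dataclasses.asdict(c) for c in self.baseline_covariates
        ]
        d["dispensing_spec"] = dataclasses.asdict(self.dispensing_spec)
        d["med_classes"] = list(self.med_classes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["baseline_covariates"] = [
            CovariateSpec(**c) for c in d["baseline_covariates"]
        ]
        if "dispensing_spec" in d:
            spec = dict(d["dispensing_spec"])
            spec["supplies"] = tuple(spec["supplies"])
            spec["supply_probs"] = tuple(spec["supply_probs"])
            d["dispensing_spec"] = DispensingSpec(**spec)
        d["med_classes"] = tuple(d["med_classes"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def linear_predictor(
    coefs: dict[str, float],
    values: dict[str, np.ndarray],
    exposure: np.ndarray | None = None,
    exposure_classes: tuple[str, ...] = (),
) -> np.ndarray:
    """Evaluate a named-coefficient linear predictor over patient arrays.

    ``exposure`` is an (n, n_classes) 0/1 matrix of current exposure status;
    the 'exposure' key of ``coefs`` maps class labels to coefficients.
    """
    n = len(next(iter(values.values())))
    lp = np.full(n, float(coefs.get("intercept", 0.0)))
    for name, coef in coefs.items():
        if name in RESERVED_KEYS:
            continue
        lp += coef * values[name]
    if exposure is not None and "exposure" in coefs:
        for med, coef in coefs["exposure"].items():  # type: ignore[union-attr]
            lp += coef * exposure[:, exposure_classes.index(med)]
    return lp


def expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))
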