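"""New-user cohort construction with washout and eligibility attrition.

Implements the active-comparator new-user design: an index fill qualifies
when the patient has no dispensing of any compared medication class during
the washout window before it, and ordered exclusion predicates are then
applied with first-failure attribution so the attrition flow conserves
counts exactly (new fills = index fills + sum of exclusions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

DEFAULT_WASHOUT_DAYS = 730

# Predicate signature: (patient_row: pd.Series, index_day: int) -> bool,
# returning True when the patient must be EXCLUDED at that index date.
Predicate = Callable[[pd.Series, int], bool]


class CohortError(ValueError):
    """Raised for invalid cohort-construction input."""


@dataclass
class EligibilityCriteria:
    compared_classes: Sequence[str]
    washout_days: int = DEFAULT_WASHOUT_DAYS
    exclusion_predicates: Sequence[tuple[str, Predicate]] = ()

    def __post_init__(self) -> None:
        if not (2 <= len(set(self.compared_classes)) <= 4):
            raise CohortError(
                "compared_classes needs 2-4 distinct entries, got "
                f"{list(self.compared_classes)}"
            )
        if self.washout_days <= 0:
            raise CohortError("washout_days must be positive")
        labels = [label for label, _ in self.exclusion_predicates]
        if len(labels) != len(set(labels)):
            raise CohortError(f"duplicate exclusion labels in {labels}")


@dataclass
class AttritionReport:
    """Sequential-flow attrition accounting.

    Each candidate fill is counted against the first failing predicate only,
    so ``n_new_fills == n_index_fills + sum(exclusions.values())``.
    """

    n_new_fills: int
    exclusions: dict[str, int]
    n_index_fills: int
    arm_counts: dict[str, int]
    followup_end_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("new_fills", "", self.n_new_fills)]
        rows += [("excluded", lab, n) for lab, n in self.exclusions.items()]
        rows.append(("index_fills", "", self.n_index_fills))
        rows += [("arm", arm, n) for arm, n in sorted(self.arm_counts.items())]
        for arm, causes in sorted(self.followup_end_counts.items()):
            rows += [
                ("followup_end", f"{arm}:{cause}", n)
                for cause, n in sorted(causes.items())
            ]
        return pd.DataFrame(rows, columns=["stage", "label", "count"])

    def to_text(self) -> str:
        lines = [f"New-user index fills screened: {self.n_new_fills}"]
        for label, n in self.exclusions.items():
            lines.append(f"  excluded ({label}): {n}")
        lines.append(f"Index fills entering cohort: {self.n_index_fills}")
        for arm, n in sorted(self.arm_counts.items()):
            lines.append(f"  arm {arm}: {n}")
        return "\n".join(lines)


def identify_new_users(
    dispensings: pd.DataFrame, criteria: EligibilityCriteria
) -> pd.DataFrame:
    """Candidate index fills under the new-user washout rule.

    A fill of a compared class at day d qualifies iff no OTHER dispensing of
    any compared class falls in the window (d - washout_days, d]: a fill
    exactly ``washout_days`` earlier does not block, a same-day fill of
    another compared class does (ambiguous dual initiation blocks both).
    Same-day duplicates of the same class count as one initiation event.
    At most one candidate per patient: the earliest qualifying fill.
    """
    compared = list(dict.fromkeys(criteria.compared_classes))
    if not compared:
        raise CohortError("compared_classes is empty")
    sub = dispensings[dispensings["med_class"].isin(compared)]
    out: list[tuple[object, int, str]] = []
    for pid, grp in sub.groupby("patient_id", sort=True):
        fills = (
            grp[["dispense_day", "med_class"]]
            .drop_duplicates()
            .sort_values(["dispense_day", "med_class"])
        )
        days = fills["dispense_day"].to_numpy()
        meds = fills["med_class"].to_numpy()
        for day, med in zip(days, meds):
            blocked = (
                (days > day - criteria.washout_days)
                & (days <= day)
                & ((days != day) | (meds != med))
            ).any()
            if not blocked:
                out.append((pid, int(day), med))
                break  # earliest qualifying fill per patient
    return pd.DataFrame(out, columns=["patient_id", "index_day", "index_class"])


def apply_eligibility(
    candidates: pd.DataFrame,
    patients: pd.DataFrame,
    criteria: EligibilityCriteria,
) -> tuple[pd.DataFrame, AttritionReport]:
    """Apply ordered exclusion predicates with first-failure attribution."""
    patients = patients.set_index("patient_id", drop=False)
    missing = set(candidates["patient_id"]) - set(patients.index)
    if missing:
        raise CohortError(f"candidates without patient records: {missing}")

    exclusions = {label: 0 for label, _ in criteria.exclusion_predicates}
    keep: list[bool] = []
    for _, cand in candidates.iterrows():
        row = patients.loc[cand["patient_id"]]
        failed = None
        for label, pred in criteria.exclusion_predicates:
            try:
                hit = bool(pred(row, int(cand["index_day"])))
            except Exception as exc:  # noqa: BLE001 - rewrap with context
                raise CohortError(
                    f"exclusion predicate {label!r} raised for patient "
                    f"{cand['patient_id']!r}: {exc}"
                ) from exc
            if hit:
                failed = label
                break
        if failed is not None:
            exclusions[failed] += 1
        keep.append(failed is None)

    cohort = candidates.loc[keep].reset_index(drop=True)
    report = AttritionReport(
        n_new_fills=len(candidates),
        exclusions=exclusions,
        n_index_fills=len(cohort),
        arm_counts=cohort["index_class"].value_counts().to_dict(),
    )
    return cohort, report
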