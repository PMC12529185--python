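"""Dispensing-derived medication exposure timelines.

Pharmacy fills are converted into daily exposure status with two rules:

* each dispensing covers the half-open day interval starting on the dispense
  day and lasting twice the days' supply (the doubled window absorbs
  imperfect adherence and stockpiling);
* a gap between the end of the running coverage and the next dispensing of
  the same medication is bridged -- the gap days count as exposed -- when it
  is at most ``max_gap_days`` (default 90); a longer gap splits exposure and
  marks treatment discontinuation at the end of the preceding coverage.

Coverage periods of overlapping fills are unioned: an early refill never
shortens coverage already granted by a prior fill, and no stockpiling credit
extends a fill beyond its own doubled window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_MAX_GAP_DAYS = 90
COVERAGE_MULTIPLIER = 2


class ExposureError(ValueError):
    """Raised for invalid dispensing input."""


@dataclass(frozen=True)
class DispensingRecord:
    """One pharmacy fill."""

    patient_id: object
    med_class: str
    dispense_day: int
    days_supply: int

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ExposureError(
                f"days_supply must be >= 1, got {self.days_supply}"
            )
        if self.dispense_day < 0:
            raise ExposureError(
                f"dispense_day must be >= 0, got {self.dispense_day}"
            )


@dataclass
class ExposureTimeline:
    """Merged exposed intervals for one patient x one medication.

    ``intervals`` are sorted, disjoint half-open day intervals during which
    the patient counts as exposed.  ``discontinuation_day`` is the end of the
    coverage period preceding the first over-limit gap (or of the final
    period when no gap exceeds the limit): the day treatment is considered
    stopped for per-protocol purposes.
    """

    patient_id: object
    med_class: str
    intervals: list[tuple[int, int]] = field(default_factory=list)
    discontinuation_day: int | None = None

    def covered_on(self, day: int) -> bool:
        return any(s <= day < e for s, e in self.intervals)

    def first_covered_day_after(self, day: int) -> int | None:
        """Earliest covered day strictly after ``day``."""
        for s, e in self.intervals:
            if e <= day + 1:
                continue
            return max(s, day + 1)
        return None

    def exposed_days(self) -> set[int]:
        out: set[int] = set()
        for s, e in self.intervals:
            out.update(range(s, e))
        return out

    def to_frame(self) -> pd.DataFrame:
        """BED-like 3-column interval table."""
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "start_day": [s for s, _ in self.intervals],
                "end_day": [e for _, e in self.intervals],
                "med_class": self.med_class,
            }
        )


def coverage_period(record: DispensingRecord) -> tuple[int, int]:
    """Half-open coverage interval of a single fill: [day, day + 2*supply)."""
    return (
        record.dispense_day,
        record.dispense_day + COVERAGE_MULTIPLIER * record.days_supply,
    )


def build_timeline(
    records: Sequence[DispensingRecord],
    max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
) -> ExposureTimeline:
    """Merge one patient's fills of one medication into exposed intervals.

    Consecutive coverage periods whose gap (next dispense day minus running
    coverage end) is <= ``max_gap_days`` are merged, gap days included.  A
    larger gap splits exposure; the first such split fixes
    ``discontinuation_day``.
    """
    if not records:
        raise ExposureError("no dispensing records supplied")
    patients = {r.patient_id for r in records}
    meds = {r.med_class for r in records}
    if len(patients) > 1 or len(meds) > 1:
        raise ExposureError(
            f"records mix patients {patients} or medications {meds}"
        )

    fills = sorted(records, key=lambda r: (r.dispense_day, r.days_supply))
    intervals: list[tuple[int, int]] = []
    cur_start, cur_end = coverage_period(fills[0])
    for rec in fills[1:]:
        start, end = coverage_period(rec)
        if start - cur_end <= max_gap_days:
            # Merge; gap days (if any) count as exposed.  The running end is
            # the max over fills so a nested short fill never truncates.
            cur_end = max(cur_end, end)
        else:
            intervals.append((cur_start, cur_end))
            cur_start, cur_end = start, end
    intervals.append((cur_start, cur_end))

    # Discontinuation = end of the first exposure episode.
    return ExposureTimeline(
        patient_id=fills[0].patient_id,
        med_class=fills[0].med_class,
        intervals=intervals,
        discontinuation_day=intervals[0][1],
    )


def detect_deviation(
    timelines: dict[str, ExposureTimeline],
    index_class: str,
    comparator_classes: Iterable[str],
    index_day: int,
    horizon_day: int | None = None,
) -> tuple[int | None, str]:
    """First treatment-protocol deviation after the index fill.

    Returns ``(deviation_day, kind)`` where kind is ``"discontinuation"``,
    ``"crossover"`` or ``"none"``.  The deviation day is the earlier of the
    first day no longer covered by the index-class exposure episode
    containing the index day, and the first covered day of any comparator
    class after the index day; a tie is classified as crossover.  With a
    ``horizon_day``, deviations at or beyond it are ignored.
    """
    index_tl = timelines.get(index_class)
    if index_tl is None:
        raise ExposureError(f"no timeline for index class {index_class!r}")
    episode = next(
        ((s, e) for s, e in index_tl.intervals if s <= index_day < e), None
    )
    if episode is None:
        raise ExposureError(
            f"index day {index_day} not covered by {index_class!r}: "
            "not a true initiator"
        )
    disc_day = episode[1]

    cross_day: int | None = None
    for med in comparator_classes:
        tl = timelines.get(med)
        if tl is None or med == index_class:
            continue
        day = tl.first_covered_day_after(index_day)
        if day is not None and (cross_day is None or day < cross_day):
            cross_day = day

    if cross_day is not None and cross_day <= disc_day:
        deviation, kind = cross_day, "crossover"
    else:
        deviation, kind = disc_day, "discontinuation"
    if horizon_day is not None and deviation >= horizon_day:
        return None, "none"
    return deviation, kind


def timelines_from_dispensings(
    dispensings: pd.DataFrame,
    max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
) -> dict[object, dict[str, ExposureTimeline]]:
    """Build per-patient, per-medication timelines from a dispensing table.

    Expects columns ``patient_id, med_class, dispense_day, days_supply``.
    """
    out: dict[object, dict[str, ExposureTimeline]] = {}
    for (pid, med), grp in dispensings.groupby(
        ["patient_id", "med_class"], sort=True
    ):
        records = [
            DispensingRecord(pid, med, int(d), int(s))
            for d, s in zip(grp["dispense_day"], grp["days_supply"])
        ]
        out.setdefault(pid, {})[med] = build_timeline(records, max_gap_days)
    return out


def timelines_to_frame(
    timelines: dict[object, dict[str, ExposureTimeline]]
) -> pd.DataFrame:
    """Export all timelines as one BED-like interval table."""
    frames = [
        tl.to_frame() for meds in timelines.values() for tl in meds.values()
    ]
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "start_day", "end_day", "med_class"]
        )
    return pd.concat(frames, ignore_index=True)
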