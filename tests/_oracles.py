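"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results day by day from the stated rules,
sharing no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def exposed_days_bruteforce(
    fills: list[tuple[int, int]], max_gap: int = 90
) -> set[int]:
    """Day-by-day exposure per the coverage-and-gap rule.

    ``fills`` are (dispense_day, days_supply) pairs for one patient and one
    medication.  A day is exposed if it falls inside any fill's doubled
    coverage window, or inside an allowable gap: after the latest coverage
    end among prior fills but before the next dispensing, with that span at
    most ``max_gap`` days.
    """
    if not fills:
        return set()
    horizon = max(d + 2 * s for d, s in fills) + 1
    days: set[int] = set()
    for day in range(horizon):
        if any(d <= day < d + 2 * s for d, s in fills):
            days.add(day)
            continue
        prior_ends = [d + 2 * s for d, s in fills if d <= day]
        later_fills = [d for d, _ in fills if d > day]
        if not prior_ends or not later_fills:
            continue
        p = max(prior_ends)
        if p <= day and min(later_fills) - p <= max_gap:
            days.add(day)
    return days


def deviation_bruteforce(
    fills_by_med: dict[str, list[tuple[int, int]]],
    index_class: str,
    index_day: int,
    max_gap: int = 90,
):
    """Day-level protocol deviation from brute-force exposed-day sets."""
    exp = exposed_days_bruteforce(fills_by_med.get(index_class, []), max_gap)
    assert index_day in exp, "index day must be covered"
    day = index_day
    while day in exp:
        day += 1
    disc_day = day
    cross_day = None
    for med, fills in fills_by_med.items():
        if med == index_class:
            continue
        other = exposed_days_bruteforce(fills, max_gap)
        after = [d for d in other if d > index_day]
        if after:
            c = min(after)
            if cross_day is None or c < cross_day:
                cross_day = c
    if cross_day is not None and cross_day <= disc_day:
        return cross_day, "crossover"
    return disc_day, "discontinuation"


def covariate_panel_bruteforce(
    meas: list[tuple[int, str, float]],
    index_day: int,
    names_kinds: dict[str, str],
    horizon_intervals: int,
    baseline_fill: dict[str, float],
    baseline_window_days: int = 365,
):
    """Per-day scan giving (value, indicator) per covariate per interval."""
    out = {}
    for name in names_kinds:
        vals, inds = [], []
        obs = sorted(
            [(d, v) for d, n, v in meas if n == name],
            key=lambda t: t[0],
        )
        for k in range(horizon_intervals):
            lo = index_day + 30 * k
            hi = lo + 30
            in_interval = [(d, v) for d, v in obs if lo <= d < hi]
            inds.append(1 if in_interval else 0)
            upto = [
                (d, v)
                for d, v in obs
                if index_day - baseline_window_days <= d < hi
            ]
            vals.append(upto[-1][1] if upto else baseline_fill[name])
        out[name] = (vals, inds)
    return out


def person_rows_bruteforce(
    index_day: int,
    arm: str,
    fills_by_med: dict[str, list[tuple[int, int]]],
    event_days: list[int],
    death: tuple[int, str] | None,
    enroll_end: int,
    admin_end_day: int,
    mode: str,
    horizon_intervals: int,
    outcome_death_causes: set[str],
):
    """Day-resolution follow-up for one patient, collapsed to intervals.

    Returns ``(k_term, y_term, censor_kind, A_per_interval, adherent)``
    using the stated conventions: earliest terminal cause with interval-
    level precedence outcome > death > disenrollment > admin end, and
    day-level resolution of the per-protocol artificial censoring.
    """
    H = horizon_intervals
    cand = []  # (k, precedence, kind, day)
    out_days = [d for d in event_days if d >= index_day]
    if death is not None and death[1] in outcome_death_causes:
        out_days.append(death[0])
    if out_days:
        d = min(out_days)
        if (d - index_day) // 30 < H:
            cand.append(((d - index_day) // 30, -1, "outcome", d))
    if death is not None and death[1] not in outcome_death_causes:
        d = death[0]
        kind = (
            "unknown_death" if death[1] == "unknown" else "noncv_death"
        )
        if 0 <= (d - index_day) // 30 < H:
            cand.append(((d - index_day) // 30, 0, kind, d))
    if enroll_end < admin_end_day and (
        death is None or death[0] > enroll_end
    ):
        if 0 <= (enroll_end - index_day) // 30 < H:
            cand.append(
                ((enroll_end - index_day) // 30, 1, "disenrollment",
                 enroll_end)
            )
    if (admin_end_day - index_day) // 30 < H:
        cand.append(
            ((admin_end_day - index_day) // 30, 2, "admin_end",
             admin_end_day)
        )

    dev_day, _ = deviation_bruteforce(fills_by_med, arm, index_day)
    k_dev = (dev_day - index_day) // 30

    if cand:
        k_o, _, kind_o, day_o = min(cand)
    else:
        k_o, kind_o, day_o = H, "completed", None
    if mode == "PP" and k_dev < H and (
        k_dev < k_o or (k_dev == k_o and dev_day <= day_o)
    ):
        k_term, kind = k_dev, "artificial_pp"
    elif k_o < H:
        k_term, kind = k_o, kind_o
    else:
        k_term, kind = H - 1, "completed"

    exp = exposed_days_bruteforce(fills_by_med.get(arm, []))
    A = [int(index_day + 30 * k in exp) for k in range(k_term + 1)]
    y_term = int(kind == "outcome")
    censor = kind if kind not in ("outcome", "completed") else "none"
    adherent = [
        k < k_dev or (k == k_dev and y_term == 1 and k == k_term)
        for k in range(k_term + 1)
    ]
    return k_term, y_term, censor, A, adherent


def random_fill_set(rng: np.random.Generator, max_fills: int = 20):
    """A randomized dispensing pattern exercising merges, gaps and overlaps."""
    n = int(rng.integers(1, max_fills + 1))
    days = np.sort(rng.integers(0, 700, size=n))
    supplies = rng.choice([1, 7, 15, 30, 60, 90], size=n)
    return [(int(d), int(s)) for d, s in zip(days, supplies)]
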