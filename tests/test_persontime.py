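"""Person-interval dataset: terminal logic, precedence, missingness coding."""

import pandas as pd
import pytest

from ttemul import generate_population, scenarios, timelines_from_dispensings
from ttemul.persontime import (
    OutcomeDefinition,
    PersonTimeError,
    ProtocolSpec,
    build_long_dataset,
    encode_missingness,
)

from _oracles import person_rows_bruteforce


def frame(rows, cols):
    return pd.DataFrame(rows, columns=cols)


def make_inputs(
    fills,
    events=(),
    death=None,
    enroll_end=900,
    extra_measurements=(),
):
    """One-patient raw tables: fills (med, day, supply), events (day, type)."""
    patients = frame(
        [(1, 0, enroll_end,
          death[0] if death else pd.NA,
          death[1] if death else pd.NA)],
        ["patient_id", "enrollment_start", "enrollment_end", "death_day",
         "death_cause"],
    )
    patients["death_day"] = patients["death_day"].astype("Int64")
    dispensings = frame(
        [(1, m, d, s) for m, d, s in fills],
        ["patient_id", "med_class", "dispense_day", "days_supply"],
    )
    meas = frame(
        [(1, d, c, v) for d, c, v in extra_measurements]
        or [(1, 0, "x", 1.0)],
        ["patient_id", "day", "covariate", "value"],
    )
    ev = frame(
        [(1, d, t) for d, t in events], ["patient_id", "day", "event_type"]
    )
    cohort = frame([(1, 0, fills[0][0])],
                   ["patient_id", "index_day", "index_class"])
    tls = timelines_from_dispensings(dispensings)
    return cohort, tls, meas, ev, patients


KINDS = {"x": "continuous"}


def build(mode="PP", horizon=30, admin=900, **kwargs):
    cohort, tls, meas, ev, patients = make_inputs(**kwargs)
    spec = ProtocolSpec(mode=mode, horizon_intervals=horizon)
    return build_long_dataset(
        cohort, tls, meas, ev, patients, spec, KINDS,
        compared_classes=("su", "glp1ra"), admin_end_day=admin,
    )


class TestTerminalLogic:
    def test_event_day45_gives_rows_k0_k1(self):
        df = build(fills=[("su", 0, 90)], events=[(45, "MI")])
        assert list(df["k"]) == [0, 1]
        assert list(df["Y"]) == [0, 1]
        assert list(df["censor"]) == ["none", "none"]

    def test_pp_deviation_day60_censors_interval_2(self):
        # single 30-day fill: coverage [0, 60), deviation day 60 -> k=2
        df = build(fills=[("su", 0, 30)], horizon=10)
        assert list(df["k"]) == [0, 1, 2]
        assert df.iloc[-1]["censor"] == "artificial_pp"
        assert not df.iloc[-1]["adherent"]
        assert df.iloc[-1]["Y"] == 0

    def test_itt_ignores_deviation(self):
        df = build(mode="ITT", fills=[("su", 0, 30)], horizon=10, admin=300)
        assert list(df["k"]) == list(range(10))
        assert (df["censor"] == "none").all()

    def test_outcome_precedence_over_disenrollment_same_interval(self):
        df = build(
            fills=[("su", 0, 90)], events=[(40, "CVA")], enroll_end=35,
        )
        last = df.iloc[-1]
        assert last["Y"] == 1 and last["censor"] == "none"

    def test_deviation_day_precedes_same_interval_event(self):
        # coverage ends day 60; event on day 70 is off-protocol in PP
        df = build(fills=[("su", 0, 30)], events=[(70, "MI")], horizon=10)
        assert df.iloc[-1]["censor"] == "artificial_pp"
        assert df["Y"].sum() == 0
        itt = build(
            mode="ITT", fills=[("su", 0, 30)], events=[(70, "MI")],
            horizon=10,
        )
        assert itt.iloc[-1]["Y"] == 1

    def test_event_before_deviation_day_counts(self):
        df = build(fills=[("su", 0, 30)], events=[(55, "MI")], horizon=10)
        last = df.iloc[-1]
        assert last["k"] == 1 and last["Y"] == 1 and last["adherent"]

    def test_cv_death_is_outcome_noncv_death_censors(self):
        df = build(fills=[("su", 0, 90)], death=(50, "cardiovascular"))
        assert df.iloc[-1]["Y"] == 1
        df2 = build(fills=[("su", 0, 90)], death=(50, "noncardiovascular"))
        assert df2.iloc[-1]["censor"] == "noncv_death"
        df3 = build(fills=[("su", 0, 90)], death=(50, "unknown"))
        assert df3.iloc[-1]["censor"] == "unknown_death"

    def test_expanded_death_definition_turns_censor_into_outcome(self):
        cohort, tls, meas, ev, patients = make_inputs(
            fills=[("su", 0, 90)], death=(50, "unknown")
        )
        spec = ProtocolSpec(
            mode="PP", horizon_intervals=30,
            outcome=OutcomeDefinition(
                death_causes=frozenset({"cardiovascular", "unknown"})
            ),
        )
        df = build_long_dataset(
            cohort, tls, meas, ev, patients, spec, KINDS,
            compared_classes=("su", "glp1ra"), admin_end_day=900,
        )
        assert df.iloc[-1]["Y"] == 1

    def test_event_before_index_is_an_error(self):
        cohort, tls, meas, ev, patients = make_inputs(
            fills=[("su", 60, 90)], events=[(10, "MI")]
        )
        cohort["index_day"] = 60
        with pytest.raises(PersonTimeError, match="before index"):
            build_long_dataset(
                cohort, tls, meas, ev, patients,
                ProtocolSpec(mode="PP", horizon_intervals=10), KINDS,
                compared_classes=("su", "glp1ra"), admin_end_day=900,
            )

    def test_completer_has_no_terminal_mark(self):
        fills = [("su", 30 * j, 30) for j in range(10)]
        df = build(fills=fills, horizon=5, admin=900)
        assert len(df) == 5
        assert (df["censor"] == "none").all() and df["Y"].sum() == 0


class TestEncodeMissingness:
    def panel(self, meas_rows, kinds, n_pat=2, K=5):
        meas = frame(meas_rows, ["patient_id", "day", "covariate", "value"])
        index_days = pd.Series([0] * n_pat, index=range(1, n_pat + 1))
        return encode_missingness(meas, index_days, kinds, K)

    def test_locf_between_observations(self):
        L, M = self.panel(
            [(1, 0, "x", 5.0), (1, 95, "x", 7.0), (2, 0, "x", 1.0)],
            {"x": "continuous"},
        )
        # observed at k=0 and k=3; at k=2 the k=0 value carries forward
        assert L["x"].at[1, 2] == 5.0
        assert M["x"].at[1, 2] == 0
        assert L["x"].at[1, 3] == 7.0 and M["x"].at[1, 3] == 1

    def test_unobserved_baseline_imputed_with_cohort_mean(self):
        L, M = self.panel(
            [(1, 0, "x", 8.6)], {"x": "continuous"}, n_pat=2
        )
        assert L["x"].at[2, 0] == pytest.approx(8.6)
        assert M["x"].at[2, 0] == 0

    def test_categorical_uses_mode(self):
        L, _ = self.panel(
            [(1, 0, "c", 1.0), (2, 0, "c", 1.0), (3, 5, "c", 0.0)],
            {"c": "binary"}, n_pat=4,
        )
        assert L["c"].at[4, 0] == 1.0

    def test_two_measurements_in_one_interval_later_wins(self):
        """Tie-break cross-checked against a per-day scan."""
        rows = [(1, 3, "x", 2.0), (1, 17, "x", 9.0), (2, 0, "x", 1.0)]
        L, M = self.panel(rows, {"x": "continuous"})
        assert L["x"].at[1, 0] == 9.0 and M["x"].at[1, 0] == 1
        # per-day oracle
        from _oracles import covariate_panel_bruteforce

        vals, inds = covariate_panel_bruteforce(
            [(d, c, v) for _, d, c, v in rows[:2]], 0, {"x": "continuous"},
            5, {"x": 0.0},
        )["x"]
        assert vals == list(L["x"].loc[1])
        assert inds == list(M["x"].loc[1])

    def test_no_baseline_anywhere_is_an_error(self):
        with pytest.raises(PersonTimeError, match="no observed baseline"):
            self.panel([(1, 40, "x", 1.0)], {"x": "continuous"})


class TestAgainstDayResolutionOracle:
    @pytest.mark.parametrize("mode", ["PP", "ITT"])
    def test_long_dataset_matches_bruteforce(self, mode):
        """On a small generated population, terminal interval, outcome,
        censor kind, exposure and adherence match a day-resolution
        re-derivation for every patient."""
        cfg = scenarios.default_scenario(
            n_patients=50, seed=31, horizon_days=360
        )
        tables = generate_population(cfg)
        tls = timelines_from_dispensings(tables.dispensings)
        first = tables.dispensings[
            tables.dispensings["dispense_day"] == 0
        ].drop_duplicates("patient_id")
        counts = tables.dispensings[
            tables.dispensings["dispense_day"] == 0
        ].groupby("patient_id")["med_class"].nunique()
        clean = counts[counts == 1].index  # skip dual initiators
        cohort = first[first["patient_id"].isin(clean)][
            ["patient_id", "med_class"]
        ].rename(columns={"med_class": "index_class"})
        cohort["index_day"] = 0
        kinds = {c.name: "continuous" for c in cfg.baseline_covariates}
        spec = ProtocolSpec(mode=mode, horizon_intervals=12)
        df = build_long_dataset(
            cohort, tls, tables.measurements, tables.events,
            tables.patients, spec, kinds,
            compared_classes=cfg.med_classes,
            admin_end_day=cfg.horizon_days,
        )
        pats = tables.patients.set_index("patient_id")
        for pid, grp in df.groupby("patient_id"):
            grp = grp.sort_values("k")
            fills_by_med = {
                med: [
                    (int(r.dispense_day), int(r.days_supply))
                    for r in sub.itertuples()
                ]
                for med, sub in tables.dispensings[
                    tables.dispensings["patient_id"] == pid
                ].groupby("med_class")
            }
            ev_days = sorted(
                tables.events[tables.events["patient_id"] == pid]["day"]
            )
            death = None
            if not pd.isna(pats.at[pid, "death_day"]):
                death = (
                    int(pats.at[pid, "death_day"]),
                    str(pats.at[pid, "death_cause"]),
                )
            k_term, y_term, censor, A, adherent = person_rows_bruteforce(
                index_day=0,
                arm=str(grp["arm"].iloc[0]),
                fills_by_med=fills_by_med,
                event_days=ev_days,
                death=death,
                enroll_end=int(pats.at[pid, "enrollment_end"]),
                admin_end_day=cfg.horizon_days,
                mode=mode,
                horizon_intervals=12,
                outcome_death_causes={"cardiovascular"},
            )
            if mode == "ITT":
                assert list(grp["k"]) == list(range(k_term + 1)), pid
                assert int(grp["Y"].iloc[-1]) == y_term, pid
                assert grp["censor"].iloc[-1] == censor, pid
            else:
                assert list(grp["k"]) == list(range(k_term + 1)), pid
                assert int(grp["Y"].iloc[-1]) == y_term, pid
                assert grp["censor"].iloc[-1] == censor, pid
                assert list(grp["adherent"]) == adherent, pid
            assert list(grp["A"]) == A, pid

    def test_pp_rows_are_prefix_of_itt_rows(self):
        cfg = scenarios.default_scenario(
            n_patients=80, seed=13, horizon_days=360
        )
        tables = generate_population(cfg)
        tls = timelines_from_dispensings(tables.dispensings)
        first = tables.dispensings[
            tables.dispensings["dispense_day"] == 0
        ].drop_duplicates("patient_id")
        counts = tables.dispensings[
            tables.dispensings["dispense_day"] == 0
        ].groupby("patient_id")["med_class"].nunique()
        cohort = first[first["patient_id"].isin(counts[counts == 1].index)][
            ["patient_id", "med_class"]
        ].rename(columns={"med_class": "index_class"})
        cohort["index_day"] = 0
        kinds = {c.name: "continuous" for c in cfg.baseline_covariates}
        dfs = {}
        for mode in ("PP", "ITT"):
            dfs[mode] = build_long_dataset(
                cohort, tls, tables.measurements, tables.events,
                tables.patients, ProtocolSpec(mode=mode, horizon_intervals=12),
                kinds, compared_classes=cfg.med_classes,
                admin_end_day=cfg.horizon_days,
            )
        pp_k = dfs["PP"].groupby("patient_id")["k"].max()
        itt_k = dfs["ITT"].groupby("patient_id")["k"].max()
        assert (pp_k <= itt_k.loc[pp_k.index]).all()
        # and the shared rows carry identical covariates and outcomes except
        # on the PP terminal row (which may relabel the censor cause)
        merged = dfs["PP"].merge(
            dfs["ITT"], on=["patient_id", "k"], suffixes=("_pp", "_itt")
        )
        assert len(merged) == len(dfs["PP"])
        same = merged["k"] < merged["patient_id"].map(pp_k)
        assert (
            merged.loc[same, "Y_pp"] == merged.loc[same, "Y_itt"]
        ).all()

    def test_row_count_conservation(self):
        df = build(fills=[("su", 0, 90)], events=[(100, "MI")], horizon=10)
        assert len(df) == (100 // 30) + 1
        # no rows after the first terminal row
        assert df["k"].is_monotonic_increasing
        assert (df["Y"].cumsum() <= 1).all()
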