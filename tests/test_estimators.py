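"""Product-limit, TMLE and exact g-computation estimators."""

import numpy as np

import pytest

from ttemul.estimators import (
    DiscreteLaw,
    EstimatorError,
    Regime,
    empirical_discrete_law,
    gcomp_enumerate,
    ic_variance,
    product_limit_cuminc,
    tmle_cuminc,
    unit_weights,
)
from ttemul.nuisance import (
    LearnerLibrary,
    TruncationSpec,
    cumulative_weights,
    fit_propensity_series,
)

from conftest import make_toy_long


def saturated_toy(seed=42, n=300):
    """Two-interval binary-confounder world with confounded initiation."""
    rng = np.random.default_rng(seed)
    z0 = rng.integers(0, 2, n)
    g = np.where(z0 == 1, 0.65, 0.35)
    arm = np.where(rng.random(n) < g, "a", "b")
    p0 = 0.08 + 0.1 * z0 + 0.05 * (arm == "a")
    y0 = (rng.random(n) < p0).astype(int)
    z1 = (rng.random(n) < 0.3 + 0.4 * z0).astype(int)
    p1 = 0.05 + 0.12 * z1 + 0.08 * (arm == "b")
    y1 = (rng.random(n) < p1).astype(int)
    rows = []
    for i in range(n):
        rows.append((i, 0, arm[i], 1, True, "none", int(y0[i]), float(z0[i])))
        if not y0[i]:
            rows.append(
                (i, 1, arm[i], 1, True, "none", int(y1[i]), float(z1[i]))
            )
    df = make_toy_long(rows)
    lib = LearnerLibrary(learners=("saturated",), cv_folds=2, seed=0)
    fits = {
        f"initiation:{a}": fit_propensity_series(
            df, "initiation", lib, arm=a, g_floor=0.0
        )
        for a in ("a", "b")
    }
    return df, fits


class TestProductLimit:
    def test_unit_weights_empirical_identity(self):
        """10 patients, 2 events in interval 1 of 2 -> F(1) = 0.2."""
        rows = []
        for i in range(10):
            rows.append((i, 0, "a", 1, True, "none", int(i < 2), 0.0))
            if i >= 2:
                rows.append((i, 1, "a", 1, True, "none", 0, 0.0))
        df = make_toy_long(rows)
        curve = product_limit_cuminc(
            df, unit_weights(df), Regime("a"), label="unadjusted"
        )
        assert curve.F[0] == pytest.approx(0.2)
        assert curve.F[1] == pytest.approx(0.2)

    def test_constant_weight_scale_invariance(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(40):
            y = int(rng.random() < 0.2)
            rows.append((i, 0, "a", 1, True, "none", y, 0.0))
        df = make_toy_long(rows)
        c1 = product_limit_cuminc(df, unit_weights(df), Regime("a"))
        c2 = product_limit_cuminc(df, 7.3 * unit_weights(df), Regime("a"))
        assert np.allclose(c1.F, c2.F)

    def test_weighted_toy_matches_hand_computation(self):
        """4 patients, 2 intervals, known weights.

        Interval 0: weights (2, 1, 1, 2), patient 0 has the event ->
        lambda_0 = 2/6.  Interval 1: survivors 1, 2, 3 with weights
        (1, 3, 1); patient 2 has the event -> lambda_1 = 3/5.
        F(2) = 1 - (1 - 2/6)(1 - 3/5) = 1 - 4/15.
        """
        rows = [
            (0, 0, "a", 1, True, "none", 1, 0.0),
            (1, 0, "a", 1, True, "none", 0, 0.0),
            (2, 0, "a", 1, True, "none", 0, 0.0),
            (3, 0, "a", 1, True, "none", 0, 0.0),
            (1, 1, "a", 1, True, "none", 0, 0.0),
            (2, 1, "a", 1, True, "none", 1, 0.0),
            (3, 1, "a", 1, True, "none", 0, 0.0),
        ]
        df = make_toy_long(rows)
        w = np.array([2.0, 1.0, 1.0, 2.0, 1.0, 3.0, 1.0])
        curve = product_limit_cuminc(df, w, Regime("a"))
        assert curve.F[0] == pytest.approx(2 / 6)
        assert curve.F[1] == pytest.approx(1 - (1 - 2 / 6) * (1 - 3 / 5))

    def test_unit_weight_curve_equals_kaplan_meier(self):
        """Discrete-data reduction: one minus Kaplan-Meier survival,
        cross-checked against lifelines."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        rows, durations, observed = [], [], []
        for i in range(120):
            t_event = rng.geometric(0.15)
            t_cens = rng.geometric(0.10)
            t = min(t_event, t_cens, 6)
            event = t_event <= min(t_cens, 6)
            # a censor row at interval k leaves the risk set in interval k,
            # i.e. Kaplan-Meier censoring at time k (events map to k+1)
            durations.append(t if event else t - 1)
            observed.append(event)
            for k in range(t):
                last = k == t - 1
                rows.append(
                    (i, k, "a", 1, True,
                     "disenrollment" if last and not event else "none",
                     int(last and event), 0.0)
                )
        df = make_toy_long(rows)
        curve = product_limit_cuminc(
            df, unit_weights(df), Regime("a"), horizon=6
        )
        km = KaplanMeierFitter().fit(durations, observed)
        for k in range(1, 7):
            assert curve.F[k - 1] == pytest.approx(
                1 - km.survival_function_at_times(k).iloc[0], abs=1e-12
            )

    def test_negative_weights_rejected(self):
        df = make_toy_long([(0, 0, "a", 1, True, "none", 0, 0.0)])
        with pytest.raises(EstimatorError):
            product_limit_cuminc(df, np.array([-1.0]), Regime("a"))


class TestGcompEnumerate:
    def law(self, p_high=0.3, p_low=0.1, effect=0.0):
        """2-period world: binary z0 (P=0.4 of 1), hazard depends on z and
        arm; z flips 0->1 with probability 0.5 under arm 'a' only."""
        l0 = {(0.0,): 0.6, (1.0,): 0.4}
        hazard, transition = {}, {}
        for arm_label, eff in (("a", effect), ("b", 0.0)):
            for z0 in (0.0, 1.0):
                h0 = (p_high if z0 else p_low) + eff
                hazard[(arm_label, 0, ((z0,),))] = h0
                flip = 0.5 if arm_label == "a" else 0.0
                tr = {(1.0,): flip if z0 == 0 else 1.0,
                      (0.0,): 1 - flip if z0 == 0 else 0.0}
                transition[(arm_label, 0, ((z0,),))] = tr
                for z1 in (0.0, 1.0):
                    h1 = (p_high if z1 else p_low) + eff
                    hazard[(arm_label, 1, ((z0,), (z1,)))] = h1
        return DiscreteLaw(l0=l0, hazard=hazard, transition=transition)

    def test_null_effect_exact_symmetry(self):
        law = self.law(p_high=0.2, p_low=0.2)  # hazard independent of z
        Fa = gcomp_enumerate(law, Regime("a"), 2)
        Fb = gcomp_enumerate(law, Regime("b"), 2)
        assert np.allclose(Fa, Fb)

    def test_constant_hazard_closed_form(self):
        p = 0.17
        law = DiscreteLaw(
            l0={(0.0,): 1.0},
            hazard={("a", k, ((0.0,),) + ((0.0,),) * k): p for k in range(3)},
            transition={},
        )
        F = gcomp_enumerate(law, Regime("a"), 3)
        assert np.allclose(F, 1 - (1 - p) ** np.arange(1, 4))

    def test_two_period_confounder_matches_hand_computation(self):
        """Law of total probability by hand for arm 'a':
        F(1) = 0.6*0.1 + 0.4*0.3 = 0.18
        F(2) = F(1) + 0.6*0.9*(0.5*0.3 + 0.5*0.1) + 0.4*0.7*0.3
        """
        law = self.law()
        F = gcomp_enumerate(law, Regime("a"), 2)
        f1 = 0.6 * 0.1 + 0.4 * 0.3
        f2 = f1 + 0.6 * 0.9 * (0.5 * 0.3 + 0.5 * 0.1) + 0.4 * 0.7 * 0.3
        assert F[0] == pytest.approx(f1)
        assert F[1] == pytest.approx(f2)

    def test_bad_baseline_law_rejected(self):
        with pytest.raises(EstimatorError):
            DiscreteLaw(l0={(0.0,): 0.7}, hazard={})


class TestTmle:
    def test_saturated_equivalence_with_ipw_and_gcomp(self):
        """On a 2-interval binary-confounder instance, TMLE with saturated
        nuisances, IPW with empirically saturated propensities, and exact
        enumeration of the empirical law agree to 1e-8."""
        df, fits = saturated_toy()
        law = empirical_discrete_law(df)
        for a in ("a", "b"):
            regime = Regime(a, sustained=False)
            w, _ = cumulative_weights(
                df, fits, mode="ITT", truncation=TruncationSpec(style="none")
            )
            ipw = product_limit_cuminc(df, w, regime)
            tmle = tmle_cuminc(
                df, fits, regime, horizons=[1, 2],
                q_method="saturated_history",
            )
            gcomp = gcomp_enumerate(law, regime, 2)
            assert np.max(np.abs(ipw.F - gcomp)) < 1e-8
            assert np.max(np.abs(tmle.F - gcomp)) < 1e-8

    def test_score_equation_solved(self):
        """After targeting, |mean(IC)| <= 1e-6 * sd(IC) at every horizon."""
        df, fits = saturated_toy(seed=5, n=500)
        for a in ("a", "b"):
            curve = tmle_cuminc(
                df, fits, Regime(a, sustained=False), horizons=[1, 2],
                q_method="glm",
            )
            for h in range(2):
                ic = curve.ic[:, h]
                assert abs(ic.mean()) <= 1e-6 * max(ic.std(), 1e-12)

    def test_no_events_gives_zero_risk_and_zero_ic(self):
        rows = [
            (i, k, "a", 1, True, "none", 0, float(i % 2))
            for i in range(30)
            for k in range(3)
        ]
        df = make_toy_long(rows)
        lib = LearnerLibrary(learners=("saturated",), cv_folds=2)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = {
                "initiation:a": fit_propensity_series(
                    df, "initiation", lib, arm="a"
                )
            }
            curve = tmle_cuminc(
                df, fits, Regime("a", sustained=False), horizons=[1, 2, 3],
                q_method="glm",
            )
        assert np.allclose(curve.F, 0.0)
        assert np.allclose(curve.ic, 0.0)

    def test_randomization_limit_matches_empirical_cuminc(self):
        """Without confounding or censoring, TMLE reproduces the empirical
        cumulative incidence."""
        rng = np.random.default_rng(11)
        n = 2000
        rows = []
        event_by_2 = 0
        for i in range(n):
            arm = "a" if rng.random() < 0.5 else "b"
            y0 = int(rng.random() < 0.1)
            rows.append((i, 0, arm, 1, True, "none", y0, float(rng.integers(2))))
            if not y0:
                y1 = int(rng.random() < 0.15)
                rows.append(
                    (i, 1, arm, 1, True, "none", y1,
                     float(rng.integers(2)))
                )
                event_by_2 += y1 * (arm == "a")
            else:
                event_by_2 += arm == "a"
        df = make_toy_long(rows)
        lib = LearnerLibrary(learners=("glm",), cv_folds=3, seed=0)
        fits = {
            f"initiation:{a}": fit_propensity_series(
                df, "initiation", lib, arm=a
            )
            for a in ("a", "b")
        }
        curve = tmle_cuminc(
            df, fits, Regime("a", sustained=False), horizons=[2],
            q_method="glm",
        )
        arm_a = df[(df["arm"] == "a") & (df["k"] == 0)]
        n_a = len(arm_a)
        emp = event_by_2 / n_a
        se = np.sqrt(emp * (1 - emp) / n_a)
        assert abs(curve.F[0] - emp) < 3 * se

    def test_monotone_flag_via_isotonic_projection(self):
        df, fits = saturated_toy(seed=9, n=200)
        curve = tmle_cuminc(
            df, fits, Regime("a", sustained=False), horizons=[1, 2],
            q_method="saturated_history",
        )
        assert np.all(np.diff(curve.F) >= -1e-12)


class TestIcVariance:
    def test_zero_ic_zero_se(self):
        se, ci = ic_variance(np.zeros(50), estimate=0.0)
        assert se == 0.0 and ci == (0.0, 0.0)

    def test_plus_minus_one_closed_form(self):
        ic = np.array([1.0] * 50 + [-1.0] * 50)
        se, _ = ic_variance(ic)
        assert se == pytest.approx(0.1)

    def test_too_few_values_rejected(self):
        with pytest.raises(EstimatorError):
            ic_variance(np.array([1.0]))
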