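"""Cox loss, linear/network risk models and the survival evaluation stack."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gliograph as gg
from gliograph.survival import (
    DegenerateSplitError,
    breslow_baseline,
    brier_curve,
    brier_ibs,
    composite_score,
    concordance_index,
    cox_loss,
    evaluate_risk_scores,
    fit_linear_cox,
    fit_risk_network,
    init_risk_model,
    kaplan_meier,
    logrank,
    median_split,
    _cox_loss_grad,
)


class TestCoxLoss:
    def test_single_subject_loss_zero(self):
        assert cox_loss([3.7], [1.0], [1]) == pytest.approx(0.0, abs=1e-12)

    def test_two_events_equal_scores_log2(self):
        assert cox_loss([0.0, 0.0], [1.0, 2.0], [1, 1]) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_all_censored_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert cox_loss([1.0, 2.0], [1.0, 2.0], [0, 0]) == 0.0

    def test_nan_scores_rejected(self):
        with pytest.raises(ValueError):
            cox_loss([np.nan], [1.0], [1])

    @pytest.mark.parametrize("seed", range(5))
    def test_analytic_gradient_matches_numeric(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        s = rng.normal(size=n)
        t = rng.exponential(size=n)
        d = rng.integers(0, 2, size=n)
        d[0] = 1
        l0, g = _cox_loss_grad(s, t, d)
        eps = 1e-6
        num = np.array(
            [(_cox_loss_grad(s + eps * e, t, d)[0] - l0) / eps for e in np.eye(n)]
        )
        np.testing.assert_allclose(num, g, atol=1e-5)


class TestLinearCox:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines_oracle(self, seed):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"x1": rng.normal(size=300), "x2": rng.normal(size=300)})
        tab = gg.synth.generate_survival_cohort(
            X, {"x1": 0.5, "x2": -0.3}, 24.0, 0.3, seed=seed
        )
        fit = fit_linear_cox(tab, ["x1", "x2"])
        cph = CoxPHFitter()
        cph.fit(tab[["time", "event", "x1", "x2"]], "time", "event")
        np.testing.assert_allclose(
            fit.beta.to_numpy(), cph.params_.to_numpy(), atol=1e-3
        )
        assert fit.converged

    def test_constant_column_rejected(self):
        tab = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [1, 1, 1], "x": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="constant"):
            fit_linear_cox(tab, ["x"])

    def test_ci_brackets_hr_and_p_in_range(self, survival_table):
        fit = fit_linear_cox(survival_table, ["x1", "x2"])
        assert ((fit.ci_low <= fit.hr) & (fit.hr <= fit.ci_high)).all()
        assert ((fit.p > 0) & (fit.p <= 1)).all()

    def test_null_wald_coverage(self):
        hits = 0
        n_reps = 50
        for seed in range(n_reps):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame({"x1": rng.normal(size=200)})
            tab = gg.synth.generate_survival_cohort(X, {}, 24.0, 0.3, seed=seed)
            fit = fit_linear_cox(tab, ["x1"])
            if abs(fit.beta["x1"]) < 2 * fit.se["x1"]:
                hits += 1
        assert hits >= 43  # nominal ~95% minus 3-sigma binomial slack


class TestRiskNetwork:
    def test_full_batch_linear_matches_newton_fit(self, survival_table):
        fit = fit_linear_cox(survival_table, ["x1", "x2"])
        model = fit_risk_network(
            survival_table, ["x1", "x2"], hidden_sizes=(),
            batch_size=10**9, lr=0.05, epochs=600, seed=0,
        )
        np.testing.assert_allclose(
            model.weights[0].ravel(), fit.beta.to_numpy(), atol=1e-2
        )

    def test_nonlinear_net_learns_strong_signal(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x1": rng.normal(size=500), "x2": rng.normal(size=500)})
        tab = gg.synth.generate_survival_cohort(X, {"x1": 2.0}, 24.0, 0.2, seed=2)
        train, test = tab.iloc[:350], tab.iloc[350:]
        model = fit_risk_network(
            train, ["x1", "x2"], hidden_sizes=(8,), epochs=150, seed=0
        )
        scores = model.predict(test[["x1", "x2"]])
        assert concordance_index(scores, test["time"], test["event"]) > 0.7

    def test_deterministic_per_seed(self, survival_table):
        m1 = fit_risk_network(survival_table, ["x1"], epochs=5, seed=3)
        m2 = fit_risk_network(survival_table, ["x1"], epochs=5, seed=3)
        np.testing.assert_array_equal(m1.weights[0], m2.weights[0])

    def test_json_round_trip(self, tmp_path, survival_table):
        m = fit_risk_network(survival_table, ["x1"], epochs=5, seed=0)
        m.to_json(tmp_path / "model.json")
        m2 = gg.survival.RiskModel.from_json(tmp_path / "model.json")
        x = survival_table[["x1"]]
        np.testing.assert_allclose(m.predict(x), m2.predict(x))


class TestConcordance:
    def test_perfect_anti_ordering_is_1(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(-t, t, np.ones(4, int)) == 1.0

    def test_scores_equal_times_is_0(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(t, t, np.ones(4, int)) == 0.0

    def test_brute_force_enumeration_with_censoring(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([1, 0, 1, 1])
        rng = np.random.default_rng(0)
        s = rng.normal(size=4)
        # admissible: earlier member uncensored, times distinct
        num = den = 0
        for i in range(4):
            for j in range(4):
                if t[i] < t[j] and d[i] == 1:
                    den += 1
                    num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert concordance_index(s, t, d) == pytest.approx(num / den)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(size=50)
        d = rng.integers(0, 2, size=50)
        d[:5] = 1
        s = rng.normal(size=50)  # continuous: no score ties
        c1 = concordance_index(s, t, d)
        c2 = concordance_index(-s, t, d)
        assert c1 + c2 == pytest.approx(1.0, abs=1e-12)

    def test_no_admissible_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [1.0, 2.0], [0, 0])


class TestBrier:
    def test_optimistic_prediction_equals_death_fraction(self):
        # S(t|x) = 1 everywhere, no censoring: Brier(t) = fraction dead by t
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.ones(4, int)
        grid = np.array([1.5, 2.5, 3.5])
        S = np.ones((4, 3))
        _, bs = brier_curve(S, t, d, grid)
        np.testing.assert_allclose(bs, [0.25, 0.5, 0.75])

    def test_perfect_deterministic_prediction_is_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.ones(4, int)
        grid = np.array([0.5, 1.5, 2.5, 3.5])
        S = (t[:, None] > grid[None, :]).astype(float)
        _, bs = brier_curve(S, t, d, grid)
        np.testing.assert_allclose(bs, 0.0, atol=1e-12)

    def test_oracle_beats_km_only_prediction(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        X = pd.DataFrame({"x1": x})
        tab = gg.synth.generate_survival_cohort(X, {"x1": 2.0}, 24.0, 0.2, seed=3)
        t = tab["time"].to_numpy()
        d = tab["event"].to_numpy()
        grid = np.unique(t[d == 1])
        # oracle: the generator's true exponential survival function
        rate = np.exp(2.0 * x) / 24.0
        S_oracle = np.exp(-np.outer(rate, grid))
        km = kaplan_meier(tab)
        idx = np.searchsorted(km["time"].to_numpy(), grid, side="right") - 1
        S_km = np.tile(km["survival"].to_numpy()[idx], (n, 1))
        assert brier_ibs(S_oracle, t, d, grid) < brier_ibs(S_km, t, d, grid)

    def test_ibs_within_unit_interval(self, survival_table):
        scores = survival_table["x1"].to_numpy()
        ev = evaluate_risk_scores(
            scores, survival_table["time"].to_numpy(), survival_table["event"].to_numpy()
        )
        assert 0.0 <= ev["ibs"] <= 1.0


class TestCompositeScore:
    @pytest.mark.parametrize(
        "c,ibs,expected", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.5), (0.8, 0.2, 0.8)]
    )
    def test_arithmetic(self, c, ibs, expected):
        assert composite_score(c, ibs) == expected

    def test_identity_to_machine_precision(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c, ibs = rng.random(2)
            assert composite_score(c, ibs) == (c + (1 - ibs)) / 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            composite_score(1.2, 0.0)


class TestBaselineHazard:
    def test_cumhaz_monotone_from_zero(self, survival_table):
        base = breslow_baseline(
            survival_table["x1"].to_numpy(),
            survival_table["time"].to_numpy(),
            survival_table["event"].to_numpy(),
        )
        assert base.cumulative_hazard([0.0])[0] == 0.0
        assert (np.diff(base.cumhaz) >= 0).all()
        S = base.survival([0.0, 1.0], base.times)
        assert ((S >= 0) & (S <= 1)).all()


class TestKaplanMeierLogrank:
    def test_product_limit_no_censoring(self):
        tab = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]})
        km = kaplan_meier(tab)
        np.testing.assert_allclose(
            km.set_index("time")["survival"].loc[[1.0, 2.0, 3.0, 4.0]],
            [0.75, 0.5, 0.25, 0.0],
        )

    def test_all_censored_flat_at_one(self):
        tab = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        km = kaplan_meier(tab)
        assert (km["survival"] == 1.0).all()

    def test_mixed_hand_computation(self):
        # times 1,2,3,4 with delta 1,0,1,1: S = 3/4, 3/4, 3/8, 0
        tab = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 1, 1]})
        km = kaplan_meier(tab).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(0.75)
        assert km.loc[3.0] == pytest.approx(0.375)
        assert km.loc[4.0] == pytest.approx(0.0)

    def test_identical_groups_p_one(self):
        tab = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0]})
        stat, p = logrank(tab, tab.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_power_under_strong_hazard_ratio(self):
        wins = 0
        n_reps = 40
        for seed in range(n_reps):
            rng = np.random.default_rng(2000 + seed)
            Xa = pd.DataFrame({"z": np.zeros(100)})
            Xb = pd.DataFrame({"z": np.ones(100)})
            X = pd.concat([Xa, Xb], ignore_index=True)
            tab = gg.synth.generate_survival_cohort(
                X, {"z": np.log(3.0)}, 24.0, 0.2, seed=seed
            )
            a, b = tab[tab["z"] == 0], tab[tab["z"] == 1]
            _, p = logrank(a, b)
            if p < 0.05:
                wins += 1
        assert wins >= 36

    def test_zero_events_rejected(self):
        tab = pd.DataFrame({"time": [1.0], "event": [0]})
        with pytest.raises(ValueError):
            logrank(tab, tab.copy())


class TestMedianSplit:
    def test_even_split(self):
        g = median_split(pd.Series(np.arange(1.0, 11.0)))
        assert (g == "high").sum() == 5
        assert (g == "low").sum() == 5

    def test_odd_n_median_goes_low(self):
        g = median_split(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert (g == "high").sum() == 2
        assert (g == "low").sum() == 3

    def test_ties_at_median_go_low(self):
        g = median_split(pd.Series([1.0, 2.0, 2.0, 2.0, 3.0]))
        assert (g == "high").sum() == 1

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateSplitError):
            median_split(pd.Series([1.0, 1.0, 1.0]))
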