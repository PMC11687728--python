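import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

from sbrt_radiomics import survival


def _ph_data(n, beta=0.0, seed=0, censor_scale=2.0, binary=False):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float) if binary else rng.normal(size=n)
    t = rng.exponential(np.exp(-beta * x))
    c = rng.exponential(censor_scale, n)
    return pd.DataFrame(
        {"x": x, "T": np.minimum(t, c), "E": (t <= c).astype(int)}
    )


class TestKaplanMeierLogrank:
    def test_product_limit_formula(self):
        curve = survival._km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        at_events = curve.survival[np.isin(curve.times, [1.0, 2.0, 3.0])]
        np.testing.assert_allclose(at_events, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_is_flat(self):
        curve = survival._km_curve(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        e = np.array([1, 0, 1, 1, 0] * 2)
        g = np.array([1] * 5 + [2] * 5)
        _, stat, p = survival.km_logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 60)
        e = np.ones(60, int)
        g = np.repeat([1, 2], 30)
        _, s1, p1 = survival.km_logrank(t, e, g)
        _, s2, p2 = survival.km_logrank(t, e, 3 - g)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            survival.km_logrank([1, 2, 3], [1, 1, 0], [1, 1, 1])

    def test_dichotomize_ties_to_lower_group(self):
        g = survival.dichotomize_at_median([1.0, 2.0, 2.0, 3.0])
        np.testing.assert_array_equal(g, [1, 1, 1, 2])


class TestRMST:
    def test_no_events_before_tau_gives_tau(self):
        t = np.full(50, 40.0)
        r = survival.rmst(t, np.zeros(50, int), tau=36.0)
        assert r.rmst[0][0] == pytest.approx(36.0)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, 2000)  # rate 0.1/month
        r = survival.rmst(t, np.ones(2000, int), tau=36.0)
        expected = (1 - np.exp(-3.6)) / 0.1  # 9.727 months
        assert abs(r.rmst[0][0] - expected) < 0.3

    def test_point_estimate_matches_lifelines(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(20.0, 300)
        e = (rng.random(300) < 0.7).astype(int)
        ours, _ = survival._rmst_one(t, e, 36.0)
        kmf = KaplanMeierFitter().fit(t, e)
        theirs = restricted_mean_survival_time(kmf, t=36.0)
        assert ours == pytest.approx(float(theirs), rel=1e-9)

    def test_identical_groups_no_difference(self):
        t = np.tile(np.linspace(1, 50, 25), 2)
        e = np.ones(50, int)
        g = np.repeat([1, 2], 25)
        r = survival.rmst(t, e, g, tau=36.0)
        assert r.difference == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_rectangle_sum_oracle(self):
        """RMST equals a brute-force rectangle sum of the KM step areas."""
        rng = np.random.default_rng(7)
        t = rng.exponential(15.0, 120)
        e = (rng.random(120) < 0.8).astype(int)
        tau = 30.0
        est, _ = survival._rmst_one(t, e, tau)
        kmf = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(0, tau, 300_001)
        s = kmf.survival_function_at_times(grid).to_numpy()
        brute = s.sum() * (grid[1] - grid[0])
        assert est == pytest.approx(brute, abs=2e-3)

    def test_short_follow_up_truncates_with_warning(self):
        t = np.linspace(1, 20, 30)
        with pytest.warns(UserWarning, match="truncating"):
            r = survival.rmst(t, np.ones(30, int), tau=36.0)
        assert r.tau == pytest.approx(20.0)

    def test_error_without_events_or_follow_up(self):
        with pytest.raises(ValueError):
            survival.rmst([1.0, 2.0], [0, 0], tau=36.0)


class TestBoosting:
    def test_zero_iterations_null_model(self):
        df = _ph_data(100, seed=2)
        res = survival.boost_cox(df, "T", "E", ["x"], n_iterations=0)
        assert res.selected == []
        assert (res.coefficients == 0).all()

    def test_importance_accounting_identity(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(150, 5)), columns=list("abcde"))
        lp = 0.8 * df["a"] - 0.8 * df["b"]
        t = rng.exponential(np.exp(-lp))
        c = rng.exponential(2.0, 150)
        df["T"], df["E"] = np.minimum(t, c), (t <= c).astype(int)
        res = survival.boost_cox(df, "T", "E", list("abcde"))
        assert (res.importance >= 0).all()
        assert res.importance.sum() == pytest.approx(100.0)
        assert set(res.importance.index[:2]) == {"a", "b"}

    def test_zero_path_never_selected(self):
        df = _ph_data(120, beta=1.0, seed=6)
        df["noise"] = 0.0  # constant column: can never reduce risk
        res = survival.boost_cox(df, "T", "E", ["x", "noise"])
        assert "noise" not in res.selected

    def test_zero_events_raises(self):
        df = _ph_data(30, seed=1)
        df["E"] = 0
        with pytest.raises(ValueError):
            survival.boost_cox(df, "T", "E", ["x"])

    def test_missing_values_rejected(self):
        df = _ph_data(30, seed=1)
        df.loc[0, "x"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            survival.boost_cox(df, "T", "E", ["x"])


class TestCoxFit:
    def test_binary_hr_recovery(self):
        df = _ph_data(1000, beta=np.log(2.0), seed=8, binary=True)
        fit = survival.cox_fit(df, "T", "E", ["x"])
        assert 1.7 <= fit.hazard_ratios.loc["x", "hr"] <= 2.3

    def test_iqr_scaled_hr_definition(self):
        df = _ph_data(400, beta=0.5, seed=9)
        fit = survival.cox_fit(df, "T", "E", ["x"])
        beta = fit.coefficients["x"]
        q75, q25 = np.percentile(df["x"], [75, 25])
        assert fit.hazard_ratios.loc["x", "hr"] == pytest.approx(
            np.exp(beta * (q75 - q25))
        )

    def test_score_zero_at_optimum(self):
        """The fast Newton solver lands where the partial-likelihood score
        vanishes, and agrees with the lifelines (Efron) fit on tie-free data."""
        df = _ph_data(300, beta=0.7, seed=10)
        fit = survival.cox_fit(df, "T", "E", ["x"])
        beta_fast = survival._fast_cox_newton(
            df[["x"]].to_numpy(), df["T"].to_numpy(), df["E"].to_numpy(int)
        )
        assert beta_fast[0] == pytest.approx(fit.coefficients["x"], abs=1e-5)

    def test_episode_splitting_is_neutral_without_interactions(self):
        """Splitting every subject at day 365 (with left truncation) must not
        change the estimate when no time-stratified term is requested."""
        df = _ph_data(200, beta=0.5, seed=11)
        df["T"] *= 500  # push times across the split point
        plain = survival.cox_fit(df, "T", "E", ["x"])
        split = survival._episode_split(df, "T", "E", time_strata=[], split_day=365.0)
        from lifelines import CoxPHFitter

        cph = CoxPHFitter()
        cph.fit(split[["T", "E", "x", "_entry"]], duration_col="T",
                event_col="E", entry_col="_entry")
        assert cph.params_["x"] == pytest.approx(plain.coefficients["x"], abs=1e-8)

    def test_time_stratified_fit_recovers_period_effects(self):
        rng = np.random.default_rng(12)
        n = 800
        x = rng.normal(size=n)
        # hazard ~ exp(+0.8 x) before day 365, no effect after
        t_early = rng.exponential(300 * np.exp(-0.8 * x))
        t = np.where(t_early <= 365, t_early, 365 + rng.exponential(300, n))
        df = pd.DataFrame({"x": x, "T": t, "E": np.ones(n, int)})
        fit = survival.cox_fit(df, "T", "E", ["x"], time_strata=["x"])
        assert {"x:early", "x:late"} <= set(fit.coefficients.index)
        assert fit.coefficients["x:early"] > 0.5
        assert abs(fit.coefficients["x:late"]) < 0.25


class TestCorrectedCindex:
    def test_perfectly_concordant_score(self):
        t = np.linspace(1, 100, 80)
        assert survival._cindex(
            pd.DataFrame({"T": t, "E": np.ones(80, int)}), "T", "E", -t
        ) == pytest.approx(1.0)

    def test_reversed_score_antisymmetry(self):
        t = np.linspace(1, 100, 80)
        df = pd.DataFrame({"T": t, "E": np.ones(80, int)})
        assert survival._cindex(df, "T", "E", t) == pytest.approx(0.0)

    def test_corrected_below_apparent_under_null(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(size=(60, 8)),
                          columns=[f"x{i}" for i in range(8)])
        df["T"] = rng.exponential(1.0, 60)
        df["E"] = 1
        rep = survival.corrected_cindex(df, "T", "E",
                                        [f"x{i}" for i in range(8)], B=100, seed=0)
        assert rep.corrected < rep.apparent
        assert abs(rep.corrected - 0.5) < abs(rep.apparent - 0.5)
        assert rep.ci[0] <= rep.ci[1]

    def test_too_few_bootstraps_rejected(self):
        df = _ph_data(50, seed=1)
        with pytest.raises(ValueError):
            survival.corrected_cindex(df, "T", "E", ["x"], B=5)


class TestBackwardSelection:
    def test_strong_predictor_retained_weak_removed(self):
        df = _ph_data(400, beta=1.0, seed=14)
        rng = np.random.default_rng(15)
        df["noise"] = rng.normal(size=400)
        selected = survival.backward_select(df, "T", "E", ["x", "noise"])
        assert "x" in selected
        assert "noise" not in selected

    def test_duplicated_covariate_prefiltered(self):
        df = _ph_data(300, beta=0.8, seed=16)
        df["x_copy"] = df["x"]
        imp = pd.Series({"x": 60.0, "x_copy": 40.0})
        selected = survival.backward_select(
            df, "T", "E", ["x", "x_copy"], importance=imp
        )
        assert selected == ["x"]


class TestSchoenfeld:
    def test_residual_series_shape(self):
        df = _ph_data(150, beta=0.5, seed=17)
        df["z"] = np.random.default_rng(18).normal(size=150)
        fit = survival.cox_fit(df, "T", "E", ["x", "z"])
        out = survival.schoenfeld_check(fit)
        n_events = int(df["E"].sum())
        assert set(out.index) == {"x", "z"}
        for series in out["residuals"]:
            assert len(series) == n_events

    def test_time_varying_effect_detected(self):
        """Built-in effect restricted to the first year: the PH test must
        reject in most replicates."""
        rejections = 0
        n_rep = 15
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            n = 500
            x = rng.normal(size=n)
            t_early = rng.exponential(300 * np.exp(-1.0 * x))
            t = np.where(t_early <= 365, t_early, 365 + rng.exponential(400, n))
            c = rng.uniform(200, 1500, n)
            df = pd.DataFrame({"x": x, "T": np.minimum(t, c),
                               "E": (t <= c).astype(int)})
            fit = survival.cox_fit(df, "T", "E", ["x"])
            out = survival.schoenfeld_check(fit)
            rejections += out.loc["x", "p"] < 0.05
        assert rejections / n_rep > 0.8

    def test_ph_respecting_data_rarely_rejects(self):
        rejections = 0
        n_rep = 40
        for rep in range(n_rep):
            df = _ph_data(200, beta=0.5, seed=3000 + rep)
            fit = survival.cox_fit(df, "T", "E", ["x"])
            rejections += survival.schoenfeld_check(fit).loc["x", "p"] < 0.05
        assert rejections / n_rep <= 0.15

    def test_stratified_fit_rejected(self):
        df = _ph_data(200, beta=0.5, seed=19)
        df["T"] *= 500
        fit = survival.cox_fit(df, "T", "E", ["x"], time_strata=["x"])
        with pytest.raises(ValueError, match="episode-split"):
            survival.schoenfeld_check(fit)
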