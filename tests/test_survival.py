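import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ddrmeth import (SimConfig, cox_fit, expected_survival_surface,
                     interaction_screen, km_by_cutoffs, simulate_survival)


def toy_no_ties():
    """Six observations, one binary covariate, all distinct times.

    Event/covariate pattern chosen so the partial likelihood has an
    interior maximum (no monotone-likelihood separation).
    """
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 1],
            "x": [1.0, 0.0, 0.0, 1.0, 0.0, 1.0],
            "z": [0.3, -1.0, 0.5, 0.1, -0.2, 0.8],
        },
        index=[f"s{i}" for i in range(6)],
    )


def neg_log_partial_likelihood(beta, df):
    """Hand-coded Cox partial likelihood (no ties, so Breslow = Efron)."""
    order = np.argsort(df["time"].to_numpy())
    t = df["time"].to_numpy()[order]
    e = df["event"].to_numpy()[order]
    x = df["x"].to_numpy()[order]
    ll = 0.0
    for i in range(len(t)):
        if not e[i]:
            continue
        risk = x[i:]  # later times (all distinct) are the risk set
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk)))
    return -ll


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood(self):
        df = toy_no_ties()
        fit = cox_fit(df, "x")
        ref = optimize.minimize_scalar(
            neg_log_partial_likelihood, bounds=(-10, 10), args=(df,),
            method="bounded", options={"xatol": 1e-10},
        ).x
        assert fit.coef("x") == pytest.approx(ref, abs=1e-4)

    def test_loglik_at_estimate_beats_null(self):
        df = toy_no_ties()
        fit = cox_fit(df, "x")
        assert -neg_log_partial_likelihood(fit.coef("x"), df) >= \
            -neg_log_partial_likelihood(0.0, df)

    def test_identical_groups_null_coefficient(self):
        rng = np.random.default_rng(0)
        n = 400
        df = pd.DataFrame(
            {"time": rng.exponential(10, n), "event": 1,
             "x": rng.choice([0.0, 1.0], n)},
            index=[f"s{i}" for i in range(n)],
        )
        fit = cox_fit(df, "x")
        assert abs(fit.coef("x")) <= 0.3
        assert abs(fit.terms.loc["x", "z"]) <= 3

    def test_lrt_is_twice_loglik_gap_and_nonnegative(self):
        df = toy_no_ties()
        fit = cox_fit(df, "x + z", null_formula="z")
        null_fit = cox_fit(df, "z")
        assert fit.lrt_stat == pytest.approx(
            2 * (fit.loglik - null_fit.loglik), abs=1e-10
        )
        assert fit.lrt_stat >= 0

    def test_hr_and_ci_consistent_with_coef(self):
        df = toy_no_ties()
        fit = cox_fit(df, "x")
        row = fit.terms.loc["x"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))
        assert row["ci_lower"] == pytest.approx(
            np.exp(row["coef"] - 1.96 * row["se"])
        )

    def test_no_events_rejected(self):
        df = toy_no_ties()
        df["event"] = 0
        with pytest.raises(ValueError):
            cox_fit(df, "x")


class TestInteractionScreen:
    def _cohort(self, seed=0, n=150, n_cpg=8):
        cfg = SimConfig(seed=seed)
        cfg.hazard_params.interaction_coef = -1.2
        rng = np.random.default_rng(seed)
        cpg = pd.DataFrame(rng.normal(0, 1, (n, n_cpg)),
                           index=[f"s{i}" for i in range(n)],
                           columns=[f"cg{j}" for j in range(n_cpg)])
        # survival driven by the first CpG only
        tab, _ = simulate_survival(cfg, cpg["cg0"], rng=rng)
        tab["codel"] = rng.choice([0.0, 1.0], n)
        return tab, cpg

    def test_interacting_cpg_ranks_first(self):
        tab, cpg = self._cohort()
        res = interaction_screen(tab, cpg)
        assert res["q"].idxmin() == "cg0"
        assert bool(res.loc["cg0", "flagged"])

    def test_codel_adjustment_keeps_flags_when_independent(self):
        tab, cpg = self._cohort(seed=1)
        plain = interaction_screen(tab, cpg)
        adj = interaction_screen(tab, cpg, adjust_codel=True)
        assert set(plain.index[plain["flagged"]]) == set(
            adj.index[adj["flagged"]]
        )

    def test_permuted_arms_yield_no_flags(self):
        tab, cpg = self._cohort(seed=2)
        rng = np.random.default_rng(3)
        tab = tab.copy()
        tab["arm"] = rng.permutation(tab["arm"].to_numpy())
        res = interaction_screen(tab, cpg)
        assert res["flagged"].sum() <= 1

    def test_incomplete_cpg_coverage_rejected(self):
        tab, cpg = self._cohort(seed=4)
        with pytest.raises(ValueError):
            interaction_screen(tab, cpg.iloc[:50])


class TestKaplanMeier:
    def _tab(self, seed=0, n=120):
        cfg = SimConfig(seed=seed)
        rng = np.random.default_rng(seed)
        score = pd.Series(rng.normal(0, 1, n),
                          index=[f"s{i}" for i in range(n)])
        tab, _ = simulate_survival(cfg, score, rng=rng)
        return tab, score

    def test_no_events_curve_stays_at_one(self):
        tab, score = self._tab()
        tab = tab.copy()
        tab["event"] = 0
        km = km_by_cutoffs(tab, score)
        for arm in km["arms"].values():
            for curve in arm["curves"].values():
                assert (curve["survival"] == 1.0).all()

    def test_curves_nonincreasing(self):
        tab, score = self._tab(seed=1)
        km = km_by_cutoffs(tab, score)
        for arm in km["arms"].values():
            for curve in arm["curves"].values():
                assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_default_cutoffs_are_quartiles(self):
        tab, score = self._tab(seed=2)
        km = km_by_cutoffs(tab, score)
        assert km["cutoffs"][0] == pytest.approx(score.quantile(0.25))
        assert km["cutoffs"][1] == pytest.approx(score.quantile(0.75))

    def test_empty_group_rejected(self):
        tab, score = self._tab(seed=3)
        with pytest.raises(ValueError, match="empty"):
            km_by_cutoffs(tab, score, cutoffs=(score.max() + 1,
                                               score.max() + 2))


class TestSurvivalSurface:
    def _fit(self, seed=0, n=400):
        cfg = SimConfig(seed=seed)
        rng = np.random.default_rng(seed)
        score = pd.Series(rng.normal(0, 1, n),
                          index=[f"s{i}" for i in range(n)])
        tab, _ = simulate_survival(cfg, score, rng=rng)
        return cox_fit(tab, "score + arm + score:arm"), tab

    def test_survival_starts_at_one(self):
        fit, tab = self._fit()
        surf = expected_survival_surface(fit, np.linspace(-2, 2, 5),
                                         np.array([0.0, 10.0, 20.0]))
        for sf in surf.values():
            assert np.allclose(sf.iloc[0], 1.0, atol=1e-12)

    def test_arms_coincide_where_interaction_cancels_arm_effect(self):
        fit, tab = self._fit(seed=1)
        b_arm = fit.coef("arm")
        b_int = fit.coef("score:arm")
        s_star = -b_arm / b_int
        times = np.linspace(1, 30, 10)
        surf = expected_survival_surface(fit, np.array([s_star]), times)
        assert np.allclose(surf["RT"].to_numpy(), surf["TMZ"].to_numpy(),
                           atol=1e-8)

    def test_consistent_with_per_sample_prediction(self):
        # evaluate at observed event times, where the fitted step function
        # is unambiguous, and compare with the fitter's own prediction
        fit, tab = self._fit(seed=2)
        s0 = tab.iloc[0]
        times = fit.fitter.baseline_survival_.index.to_numpy()[10:50:5]
        surf = expected_survival_surface(fit, np.array([s0["score"]]), times)
        arm_name = "TMZ" if s0["arm"] in (1.0, "TMZ") else "RT"
        df = pd.DataFrame({"score": [s0["score"]],
                           "arm": [1.0 if arm_name == "TMZ" else 0.0]})
        ref = fit.fitter.predict_survival_function(df, times=times)
        assert np.allclose(surf[arm_name].to_numpy().ravel(),
                           ref.to_numpy().ravel(), atol=1e-8)

    def test_time_grid_beyond_followup_clamped(self):
        fit, tab = self._fit(seed=3)
        with pytest.warns(UserWarning, match="clamping"):
            surf = expected_survival_surface(
                fit, np.array([0.0]), np.array([tab["time"].max() * 10])
            )
        assert all(np.isfinite(sf.to_numpy()).all() for sf in surf.values())
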