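import numpy as np
import pandas as pd
import pytest

from ddrmeth import (MgmtModel, adjust_score_for_purity, fit_mgmt_model,
                     fit_spls, mgmt_score, predict_purity,
                     score_purity_association, select_purity_predictors)


class TestMgmtScore:
    def test_zero_linear_predictor_is_methylated(self):
        model = MgmtModel(intercept=0.0, coef1=0.0, coef2=0.0)
        res = mgmt_score(np.array([1.0]), np.array([2.0]), model)
        assert res["prob"].iloc[0] == pytest.approx(0.5)
        assert res["status"].iloc[0] == "methylated"  # 0.5 > 0.358

    def test_probability_at_cutoff_is_unmethylated(self):
        # strict '>' at the classification cutoff
        model = MgmtModel(intercept=0.0, coef1=0.0, coef2=0.0, cutoff_prob=0.5)
        res = mgmt_score(np.array([0.0]), np.array([0.0]), model)
        assert res["prob"].iloc[0] == model.cutoff_prob
        assert res["status"].iloc[0] == "unmethylated"

    def test_score_is_logit_of_prob(self):
        model = MgmtModel(intercept=-1.0, coef1=0.5, coef2=0.25)
        m1 = np.array([1.0, -2.0])
        m2 = np.array([0.0, 4.0])
        res = mgmt_score(m1, m2, model)
        from scipy.special import logit

        assert np.allclose(res["score"], logit(res["prob"]), atol=1e-12)

    def test_monotone_in_positive_coefficient_input(self):
        model = MgmtModel(intercept=0.0, coef1=2.0, coef2=0.0)
        res = mgmt_score(np.array([-1.0, 0.0, 1.0]), np.zeros(3), model)
        assert res["prob"].is_monotonic_increasing

    def test_duplicate_probes_rejected(self):
        with pytest.raises(ValueError):
            MgmtModel(probe_ids=("cg1", "cg1"))

    def test_yaml_roundtrip(self, tmp_path):
        model = MgmtModel(intercept=1.5, coef1=-0.3, coef2=0.7)
        model.to_yaml(tmp_path / "m.yaml")
        back = MgmtModel.from_yaml(tmp_path / "m.yaml")
        assert back == model


class TestFitMgmtModel:
    def _data(self, seed=0, n=200, noise=1.0):
        rng = np.random.default_rng(seed)
        m1 = rng.normal(0, 2, n)
        m2 = rng.normal(0, 2, n)
        lin = 1.5 * m1 + 0.5 * m2
        y = (lin + rng.normal(0, noise, n) > 0).astype(int)
        X = pd.DataFrame({"cgA": m1, "cgB": m2})
        return X, y

    def test_refit_classifies_training_data(self):
        X, y = self._data()
        model = fit_mgmt_model(X, y)
        res = mgmt_score(X["cgA"], X["cgB"], model)
        acc = ((res["prob"] > 0.5).astype(int) == y).mean()
        assert acc >= 0.9

    def test_separable_data_warns_and_still_fits(self):
        X, y = self._data(noise=0.0)
        with pytest.warns(UserWarning, match="separation|penalised"):
            model = fit_mgmt_model(X, y)
        res = mgmt_score(X["cgA"], X["cgB"], model)
        assert ((res["prob"] > 0.5).astype(int) == y).mean() >= 0.99

    def test_swapped_probes_and_coefs_give_identical_probs(self):
        X, y = self._data(seed=1)
        model = fit_mgmt_model(X, y)
        swapped = MgmtModel(probe_ids=(model.probe_ids[1], model.probe_ids[0]),
                            intercept=model.intercept, coef1=model.coef2,
                            coef2=model.coef1)
        a = mgmt_score(X["cgA"], X["cgB"], model)
        b = mgmt_score(X["cgB"], X["cgA"], swapped)
        assert np.allclose(a["prob"], b["prob"], atol=1e-12)

    def test_single_class_rejected(self):
        X, _ = self._data()
        with pytest.raises(ValueError):
            fit_mgmt_model(X, np.ones(len(X)))

    def test_held_out_discrimination(self, small_study):
        """Refitting on generator calibration data separates the classes."""
        from sklearn.metrics import roc_auc_score

        ms, ann = small_study["ms"], small_study["ann"]
        # two promoter probes of one normally-unmethylated gene
        truth = small_study["truth"]
        state_u = truth.probe_state[truth.probe_state == "U"].index
        prom = ann[(ann["region_class"] == "promoter")
                   & ann.index.isin(state_u)]
        gene = prom["gene"].value_counts().index[0]
        probes = list(prom.index[prom["gene"] == gene][:2])
        if len(probes) < 2:
            probes = list(prom.index[:2])
        samp = ms.samples
        tumor = samp.index[samp["tissue_type"] == "tumor"]
        y = samp.loc[tumor, "cimp"].astype(int)
        M = ms.M.loc[tumor, probes]
        half = len(tumor) // 2
        model = fit_mgmt_model(M.iloc[:half], y.iloc[:half])
        res = mgmt_score(M.iloc[half:, 0], M.iloc[half:, 1], model)
        assert roc_auc_score(y.iloc[half:], res["prob"]) >= 0.95


class TestPurityPredictors:
    def _setup(self):
        probes = ["low", "boundary", "high", "prom"]
        beta = pd.DataFrame(
            {"low": [0.18, 0.19, 0.20], "boundary": [0.20, 0.20, 0.20],
             "high": [0.5, 0.6, 0.7], "prom": [0.05, 0.05, 0.05]},
            index=["s1", "s2", "s3"],
        )
        ann = pd.DataFrame(
            {"chrom": "1p", "pos": [1, 2, 3, 4], "gene": ["", "", "", "G1"],
             "tss_distance": [np.nan, np.nan, np.nan, 0],
             "region_class": ["intergenic", "intergenic", "intergenic",
                              "promoter"],
             "snp_flag": False, "sex_chrom": False, "ddr_flag": False},
            index=pd.Index(probes, name="probe_id"),
        )
        return beta, ann

    def test_strict_median_threshold(self):
        beta, ann = self._setup()
        sel = select_purity_predictors(beta, ann)
        assert sel == ["low"]  # 0.19 < 0.2 in; 0.20 excluded (strict)

    def test_promoter_probes_never_selected(self):
        beta, ann = self._setup()
        assert "prom" not in select_purity_predictors(beta, ann)

    def test_empty_selection_raises(self):
        beta, ann = self._setup()
        with pytest.raises(ValueError, match="relax"):
            select_purity_predictors(beta, ann, beta_median_max=0.01)


def purity_design(seed=0, n=150, p=500, noise=0.05):
    """Predictor betas that mix tumor and normal levels by purity."""
    rng = np.random.default_rng(seed)
    purity = rng.beta(5, 2, n)
    beta_n = rng.uniform(0.02, 0.12, p)
    delta = rng.uniform(0.05, 0.2, p)
    X = purity[:, None] * (beta_n + delta)[None, :] + \
        (1 - purity[:, None]) * beta_n[None, :]
    X = np.clip(X + rng.normal(0, noise, (n, p)), 1e-4, 0.9)
    return (pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                         columns=[f"cg{j}" for j in range(p)]),
            pd.Series(purity, index=[f"s{i}" for i in range(n)]))


class TestSpls:
    def test_eta_zero_first_weight_is_covariance_direction(self):
        X, purity = purity_design(seed=1, n=40, p=30)
        m = fit_spls(X, purity, K=1, eta=0.0)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        y = np.arcsin(np.sqrt(purity.to_numpy()))
        w_ref = Xc.T @ (y - y.mean())
        w_ref /= np.linalg.norm(w_ref)
        assert np.allclose(np.abs(m.weights[:, 0]), np.abs(w_ref), atol=1e-10)

    def test_eta_zero_matches_dense_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        X, purity = purity_design(seed=2, n=60, p=40)
        m = fit_spls(X, purity, K=3, eta=0.0)
        Xc = X.to_numpy()
        mine = (Xc - m.x_mean) @ m.coef_ + m.y_mean
        ref = PLSRegression(n_components=3, scale=False).fit(
            Xc, np.arcsin(np.sqrt(purity.to_numpy()))
        )
        assert np.abs(mine - ref.predict(Xc).ravel()).max() <= 1e-8

    def test_sparse_recovery_of_informative_probes(self):
        rng = np.random.default_rng(3)
        n, p = 80, 500
        y = rng.uniform(0.1, 1.4, n)  # already on the transformed scale
        X = rng.normal(0, 0.02, (n, p))
        for j in range(5):
            # noiseless signal probes of comparable strength, so all clear
            # the eta-fraction-of-max soft threshold
            X[:, j] = 0.1 * (1 + 0.05 * j) * y
        Xdf = pd.DataFrame(X, columns=[f"cg{j}" for j in range(p)])
        m = fit_spls(Xdf, y, K=1, eta=0.8, transform=False)
        nonzero = set(np.flatnonzero(m.weights[:, 0]))
        assert len(nonzero & {0, 1, 2, 3, 4}) >= 4
        yhat = (X - m.x_mean) @ m.coef_ + m.y_mean
        ss_res = ((y - yhat) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.99

    def test_constant_purity_rejected(self):
        X, _ = purity_design(seed=4, n=30, p=10)
        with pytest.raises(ValueError, match="zero-variance"):
            fit_spls(X, np.full(30, 0.5))

    def test_too_few_samples_rejected(self):
        X, purity = purity_design(seed=5, n=150, p=10)
        with pytest.raises(ValueError):
            fit_spls(X.iloc[:10], purity.iloc[:10])


class TestPredictPurity:
    def test_held_out_rmse(self):
        X, purity = purity_design(seed=6)
        m = fit_spls(X.iloc[:100], purity.iloc[:100], K=3, eta=0.4)
        pred = predict_purity(m, X.iloc[100:])
        rmse = float(np.sqrt(np.mean((pred - purity.iloc[100:]) ** 2)))
        assert rmse <= 0.05

    def test_predictions_clipped_to_unit_interval(self):
        X, purity = purity_design(seed=7, n=50, p=20)
        m = fit_spls(X, purity, K=2, eta=0.2)
        wild = X * 50.0
        pred = predict_purity(m, wild)
        assert pred.min() >= 0.0 and pred.max() <= 1.0

    def test_invariant_to_extra_probes(self):
        X, purity = purity_design(seed=8, n=40, p=15)
        m = fit_spls(X, purity, K=2, eta=0.2)
        extra = X.copy()
        extra["unrelated"] = 0.5
        assert np.allclose(predict_purity(m, X), predict_purity(m, extra))

    def test_missing_probes_rejected(self):
        X, purity = purity_design(seed=9, n=40, p=15)
        m = fit_spls(X, purity, K=2, eta=0.2)
        with pytest.raises(KeyError):
            predict_purity(m, X.iloc[:, :5])


class TestScorePurityAssociation:
    def test_perfect_linear_association(self):
        purity = np.linspace(0.2, 0.9, 30)
        res = score_purity_association(2.0 * purity, purity)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_residuals_orthogonal_to_purity(self):
        rng = np.random.default_rng(10)
        purity = rng.uniform(0.2, 1, 50)
        score = pd.Series(1.5 * purity + rng.normal(0, 1, 50))
        adj = adjust_score_for_purity(score, purity)
        assert abs(np.corrcoef(adj, purity)[0, 1]) <= 1e-10
        assert adj.mean() == pytest.approx(score.mean())
        assert adj.var() <= score.var()

    def test_orthogonal_purity_leaves_score_unchanged(self):
        rng = np.random.default_rng(11)
        score = pd.Series(rng.normal(0, 1, 200))
        purity = rng.uniform(0, 1, 200)  # independent of score
        adj = adjust_score_for_purity(score, purity)
        assert np.corrcoef(adj, score)[0, 1] >= 0.99

    def test_constant_purity_rejected(self):
        with pytest.raises(ValueError):
            score_purity_association(np.arange(20.0), np.full(20, 0.5))
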