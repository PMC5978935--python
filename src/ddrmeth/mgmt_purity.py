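"""MGMT-STP27-style two-probe scoring and sparse-PLS tumor purity (HMP index).

The MGMT promoter methylation status is predicted by a logistic model on
the M values of two promoter probes (in the published classifier,
cg12434587 and cg12981137); the *score* is the logit-transformed
probability and the published classification cutoff on the probability is
0.358.  The published coefficients live in the classifier's original
reports, so the model ships as a serialisable slot, and
:func:`fit_mgmt_model` calibrates one from labelled (synthetic) data.

Tumor purity is predicted from normally-unmethylated (median beta < 0.2)
intergenic probes by a sparse partial least squares (PLS1-NIPALS with lasso
soft-thresholding of the weight vectors) regression on arcsin-sqrt
transformed purity, trained on a reference purity estimate; back-transformed
predictions form the HMP (half-methylation-predicted) purity index.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.special import expit

DEFAULT_MGMT_PROBES = ("cg12434587", "cg12981137")
DEFAULT_CUTOFF = 0.358


@dataclass
class MgmtModel:
    """Two-probe logistic model for MGMT promoter methylation."""

    probe_ids: tuple[str, str] = DEFAULT_MGMT_PROBES
    intercept: float = 0.0
    coef1: float = 0.0
    coef2: float = 0.0
    cutoff_prob: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.probe_ids[0] == self.probe_ids[1]:
            raise ValueError("the two model probes must be distinct")
        if not (0.0 < self.cutoff_prob < 1.0):
            raise ValueError("cutoff_prob must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["probe_ids"] = list(self.probe_ids)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "MgmtModel":
        raw = yaml.safe_load(Path(path).read_text())
        raw["probe_ids"] = tuple(raw["probe_ids"])
        return cls(**raw)


def mgmt_score(M1, M2, model: MgmtModel) -> pd.DataFrame:
    """Score samples with a two-probe logistic model.

    ``prob`` is the inverse-logit of the linear predictor, ``score`` the
    linear predictor itself (= logit(prob)), and a sample is called
    ``methylated`` when prob > cutoff (strict).
    """
    m1 = np.asarray(M1, dtype=float)
    m2 = np.asarray(M2, dtype=float)
    if not (np.isfinite(m1).all() and np.isfinite(m2).all()):
        raise ValueError("non-finite M inputs")
    lin = model.intercept + model.coef1 * m1 + model.coef2 * m2
    prob = expit(lin)
    status = np.where(prob > model.cutoff_prob, "methylated", "unmethylated")
    index = M1.index if isinstance(M1, pd.Series) else pd.RangeIndex(len(m1))
    return pd.DataFrame(
        {"score": lin, "prob": prob, "status": status}, index=index
    )


def fit_mgmt_model(
    M_pairs: pd.DataFrame,
    labels,
    probe_ids: tuple[str, str] | None = None,
    cutoff_prob: float = DEFAULT_CUTOFF,
) -> MgmtModel:
    """Maximum-likelihood logistic calibration of a two-probe model.

    ``M_pairs`` has two columns (the probes, in order); ``labels`` is a
    binary vector (1 = methylated).  Perfect separation triggers a warning
    and an L2-penalised fallback fit.
    """
    if M_pairs.shape[1] != 2:
        raise ValueError("M_pairs must have exactly two columns")
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = sm.add_constant(M_pairs.to_numpy(dtype=float))
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.Logit(y, X).fit(disp=0)
            if np.abs(res.params).max() < 50:
                params = res.params
        except Exception:
            params = None
    if params is None:
        warnings.warn("separation or non-convergence: using penalised logistic fit")
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        params = np.asarray(res.params)
    ids = probe_ids or tuple(M_pairs.columns[:2])
    return MgmtModel(
        probe_ids=ids,
        intercept=float(params[0]),
        coef1=float(params[1]),
        coef2=float(params[2]),
        cutoff_prob=cutoff_prob,
    )


def select_purity_predictors(
    beta: pd.DataFrame, ann: pd.DataFrame, beta_median_max: float = 0.2
) -> list[str]:
    """Intergenic probes with across-sample median beta strictly below 0.2."""
    inter = ann.index[ann["region_class"] == "intergenic"]
    inter = inter.intersection(beta.columns)
    med = beta[inter].median(axis=0)
    selected = list(inter[(med < beta_median_max).to_numpy()])
    if not selected:
        raise ValueError(
            "no unmethylated intergenic predictors found; relax beta_median_max"
        )
    return selected


@dataclass
class SplsModel:
    """Sparse PLS1 purity predictor on arcsin-sqrt transformed response."""

    predictor_probe_ids: list[str]
    weights: np.ndarray        # p x K sparse weight vectors
    loadings: np.ndarray       # p x K
    q: np.ndarray              # K response loadings
    x_mean: np.ndarray
    y_mean: float
    K: int
    eta: float
    train_r2: float = float("nan")
    cv_table: pd.DataFrame | None = None

    @property
    def coef_(self) -> np.ndarray:
        """Regression coefficients on the centered predictors."""
        W, P = self.weights, self.loadings
        return W @ np.linalg.solve(P.T @ W, self.q)


def _soft_threshold(w: np.ndarray, eta: float) -> np.ndarray:
    thr = eta * np.abs(w).max()
    out = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
    norm = np.linalg.norm(out)
    if norm == 0:
        # keep the single largest-weight variable rather than an empty vector
        out = np.zeros_like(w)
        k = int(np.argmax(np.abs(w)))
        out[k] = np.sign(w[k])
        norm = 1.0
    return out / norm


def fit_spls(
    X: pd.DataFrame,
    purity,
    K: int = 3,
    eta: float = 0.4,
    transform: bool = True,
) -> SplsModel:
    """Sparse PLS1 (NIPALS) of arcsin-sqrt purity on predictor betas.

    Each component's weight vector is the dominant covariance direction
    X'y (unit norm), sparsified by lasso soft-thresholding at fraction
    ``eta`` of its largest absolute weight and re-normalised; scores
    deflate X before the next component.  ``eta = 0`` reproduces dense
    PLS1.  Requires n >= 20 and purity in [0, 1] when ``transform``.
    """
    y_raw = np.asarray(purity, dtype=float)
    if len(y_raw) < 20:
        raise ValueError("need at least 20 training samples")
    if transform:
        if (y_raw < 0).any() or (y_raw > 1).any():
            raise ValueError("purity must lie in [0, 1]")
        y = np.arcsin(np.sqrt(y_raw))
    else:
        y = y_raw.copy()
    if np.ptp(y) == 0 or np.var(y) < 1e-20:
        raise ValueError("zero-variance response: purity values all equal")
    Xm = X.to_numpy(dtype=float)
    x_mean = Xm.mean(axis=0)
    y_mean = float(y.mean())
    Xc = Xm - x_mean
    yc = y - y_mean

    if K > min(Xc.shape):
        warnings.warn(f"K truncated from {K} to {min(Xc.shape)}")
        K = min(Xc.shape)

    p = Xc.shape[1]
    W = np.zeros((p, K))
    P = np.zeros((p, K))
    q = np.zeros(K)
    Xd = Xc.copy()
    for k in range(K):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            W, P, q = W[:, :k], P[:, :k], q[:k]
            K = k
            warnings.warn("deflated covariance vanished; truncating components")
            break
        w = w / nw
        if eta > 0:
            w = _soft_threshold(w, eta)
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, q = W[:, :k], P[:, :k], q[:k]
            K = k
            break
        W[:, k] = w
        P[:, k] = Xd.T @ t / tt
        q[k] = float(yc @ t / tt)
        Xd = Xd - np.outer(t, P[:, k])

    model = SplsModel(
        predictor_probe_ids=list(X.columns),
        weights=W,
        loadings=P,
        q=q,
        x_mean=x_mean,
        y_mean=y_mean,
        K=K,
        eta=eta,
    )
    yhat = (Xc @ model.coef_) + y_mean
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    model.train_r2 = 1.0 - ss_res / ss_tot
    return model


def cv_spls(
    X: pd.DataFrame,
    purity,
    K_grid=(1, 2, 3, 4, 5),
    eta_grid=(0.0, 0.2, 0.4, 0.6, 0.8),
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[SplsModel, pd.DataFrame]:
    """Choose (K, eta) by n-fold CV mean squared error and refit on all data."""
    y = np.asarray(purity, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, n_folds)
    rows = []
    for K in K_grid:
        for eta in eta_grid:
            errs = []
            for f in folds:
                mask = np.ones(len(y), dtype=bool)
                mask[f] = False
                try:
                    m = fit_spls(X.iloc[mask], y[mask], K=K, eta=eta)
                except ValueError:
                    continue
                pred = predict_purity(m, X.iloc[~mask])
                errs.append(float(((pred.to_numpy() - y[~mask]) ** 2).mean()))
            if errs:
                rows.append((K, eta, float(np.mean(errs))))
    cv = pd.DataFrame(rows, columns=["K", "eta", "cv_mse"])
    best = cv.loc[cv["cv_mse"].idxmin()]
    model = fit_spls(X, y, K=int(best["K"]), eta=float(best["eta"]))
    model.cv_table = cv
    return model, cv


def predict_purity(model: SplsModel, X: pd.DataFrame) -> pd.Series:
    """HMP purity index: back-transform (sin^2) of the sPLS prediction,
    clipped to [0, 1].  Extra columns in X are ignored; missing model
    probes raise."""
    missing = [p for p in model.predictor_probe_ids if p not in X.columns]
    if missing:
        raise KeyError(f"missing predictor probes: {missing[:5]}")
    Xm = X[model.predictor_probe_ids].to_numpy(dtype=float)
    yhat = (Xm - model.x_mean) @ model.coef_ + model.y_mean
    yhat = np.clip(yhat, 0.0, np.pi / 2.0)
    return pd.Series(np.sin(yhat) ** 2, index=X.index, name="hmp_purity")


def score_purity_association(score, purity) -> dict:
    """OLS of score on purity: R^2 and heteroskedasticity-robust Wald p.

    The Wald test of the purity slope uses the HC3 covariance estimate.
    """
    s = np.asarray(score, dtype=float)
    u = np.asarray(purity, dtype=float)
    if len(s) < 10:
        raise ValueError("need at least 10 samples")
    if np.var(u) == 0:
        raise ValueError("constant purity regressor")
    X = sm.add_constant(u)
    res = sm.OLS(s, X).fit()
    robust = res.get_robustcov_results(cov_type="HC3")
    return {
        "r2": float(res.rsquared),
        "slope": float(res.params[1]),
        "wald_p": float(robust.pvalues[1]),
    }


def adjust_score_for_purity(score: pd.Series, purity) -> pd.Series:
    """Residualise the score on purity (OLS), re-centered to the original mean."""
    s = np.asarray(score, dtype=float)
    u = np.asarray(purity, dtype=float)
    X = sm.add_constant(u)
    res = sm.OLS(s, X).fit()
    adj = res.resid + s.mean()
    index = score.index if isinstance(score, pd.Series) else pd.RangeIndex(len(s))
    return pd.Series(adj, index=index, name="purity_adjusted_score")
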