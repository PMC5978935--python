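"""Cox proportional-hazards PFS modelling with treatment-biomarker interaction.

Centred on the predictive-marker question: does the effect of a CpG's
methylation (or of the two-probe methylation score) on progression-free
survival differ between the radiotherapy and temozolomide arms?  Each model
``time ~ cpg + arm + cpg:arm (+ codel)`` is compared by likelihood-ratio
test against its no-interaction null, with BH-FDR across the screened CpGs.
Kaplan-Meier summaries at score quartile cutoffs and the expected-survival
surface S(t | score, arm) visualise the interaction.

Model fitting is delegated to lifelines (Efron tie handling, Breslow
baseline hazard).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CoxFit:
    """Cox model summary plus LRT against a stated nested null."""

    terms: pd.DataFrame            # coef, se, hr, ci_lower, ci_upper, z, p
    loglik: float
    lrt_stat: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None
    ties: str = "efron"
    fitter: CoxPHFitter | None = None

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "coef"])


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    df = data.copy()
    if (df["time"] <= 0).any():
        raise ValueError("all times must be positive")
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")
    if "arm" in df.columns and df["arm"].dtype == object:
        levels = sorted(df["arm"].unique())
        if len(levels) == 2:
            df["arm"] = (df["arm"] == levels[-1]).astype(float)  # TMZ = 1
    return df


def cox_fit(
    data: pd.DataFrame,
    formula: str,
    null_formula: str | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Fit a Cox PH model by partial likelihood (Efron ties).

    ``data`` needs ``time`` and ``event`` columns; covariates are referenced
    by the lifelines/patsy ``formula`` (e.g. ``"score + arm + score:arm"``).
    When ``null_formula`` is given, the likelihood-ratio statistic
    2*(ll_full - ll_null) is reported with the difference in the number of
    parameters as degrees of freedom.
    """
    df = _prepare(data)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event", formula=formula,
            fit_options={"precision": 1e-9})
    summ = cph.summary
    terms = pd.DataFrame(
        {
            "coef": summ["coef"],
            "se": summ["se(coef)"],
            "hr": np.exp(summ["coef"]),
            "ci_lower": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "ci_upper": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "z": summ["z"],
            "p": summ["p"],
        }
    )
    fit = CoxFit(terms=terms, loglik=float(cph.log_likelihood_), ties=ties,
                 fitter=cph)
    if null_formula is not None:
        null = CoxPHFitter()
        null.fit(df, duration_col="time", event_col="event",
                 formula=null_formula, fit_options={"precision": 1e-9})
        stat = 2.0 * (fit.loglik - float(null.log_likelihood_))
        ddf = len(cph.params_) - len(null.params_)
        fit.lrt_stat = max(stat, 0.0)
        fit.lrt_df = ddf
        fit.lrt_p = float(stats.chi2.sf(fit.lrt_stat, ddf))
    return fit


def interaction_screen(
    data: pd.DataFrame,
    cpg_matrix: pd.DataFrame,
    adjust_codel: bool = False,
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Per-CpG treatment-interaction screen.

    For every CpG column, fits ``time ~ cpg + arm + cpg:arm`` (plus codel
    when requested, which must then be a column of ``data``) and the
    corresponding no-interaction null; reports the interaction coefficient,
    hazard ratio, Wald p, LRT p and the BH-FDR over the LRT p values.
    Per-CpG fit failures are recorded, not fatal.
    """
    samples = data.index.intersection(cpg_matrix.index)
    if len(samples) < len(data):
        raise ValueError("cpg_matrix does not cover all survival samples")
    rows = []
    for probe in cpg_matrix.columns:
        df = data.loc[samples].copy()
        df["cpg"] = cpg_matrix.loc[samples, probe].to_numpy(float)
        base = "cpg + arm" + (" + codel" if adjust_codel else "")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = cox_fit(df, f"{base} + cpg:arm", null_formula=base)
            inter = [t for t in fit.terms.index if ":" in t][0]
            rows.append(
                (probe, fit.terms.loc[inter, "coef"], fit.terms.loc[inter, "hr"],
                 fit.terms.loc[inter, "se"], fit.terms.loc[inter, "p"],
                 fit.lrt_stat, fit.lrt_p, True)
            )
        except Exception:
            rows.append((probe, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         False))
    res = pd.DataFrame(
        rows,
        columns=["probe_id", "coef", "hr", "se", "wald_p", "lrt_stat", "lrt_p",
                 "converged"],
    ).set_index("probe_id")
    q = np.full(len(res), np.nan)
    ok = res["converged"].to_numpy() & np.isfinite(res["lrt_p"].to_numpy())
    if ok.any():
        q[ok] = multipletests(res.loc[ok, "lrt_p"], method="fdr_bh")[1]
    res["q"] = q
    res["flagged"] = (res["q"] <= q_max).fillna(False)
    return res


def km_by_cutoffs(
    data: pd.DataFrame,
    score: pd.Series,
    cutoffs: tuple[float, float] | None = None,
) -> dict:
    """Kaplan-Meier curves for low/intermediate/high score groups per arm.

    Default cutoffs are the first and third quartiles of the score.  Returns
    per-arm KM curves (with Greenwood confidence bands) and the log-rank p
    across the three groups within each arm.
    """
    s = score.loc[data.index]
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("score must be finite")
    if cutoffs is None:
        cutoffs = (float(s.quantile(0.25)), float(s.quantile(0.75)))
    lo, hi = cutoffs
    group = pd.Series(
        np.where(s <= lo, "low", np.where(s > hi, "high", "intermediate")),
        index=s.index,
    )
    out = {"cutoffs": cutoffs, "groups": group, "arms": {}}
    for arm, sub in data.groupby("arm"):
        g = group.loc[sub.index]
        if (g.value_counts().reindex(["low", "intermediate", "high"]).fillna(0)
                == 0).any():
            raise ValueError(f"empty score group in arm {arm} at cutoffs {cutoffs}")
        curves = {}
        for level in ["low", "intermediate", "high"]:
            kmf = KaplanMeierFitter()
            mask = g == level
            kmf.fit(sub.loc[mask, "time"], sub.loc[mask, "event"], label=level)
            tab = kmf.survival_function_.join(kmf.confidence_interval_)
            tab.columns = ["survival", "ci_lower", "ci_upper"]
            curves[level] = tab
        lr = multivariate_logrank_test(sub["time"], g, sub["event"])
        out["arms"][arm] = {"curves": curves, "logrank_p": float(lr.p_value)}
    return out


def expected_survival_surface(
    fit: CoxFit,
    score_grid: np.ndarray,
    time_grid: np.ndarray,
    score_col: str = "score",
    arm_col: str = "arm",
) -> dict[str, pd.DataFrame]:
    """Expected survival S(t | score) per arm from a fitted interaction model.

    Uses the fitted model's Breslow baseline hazard; times beyond the last
    observed event are clamped to it (with a warning).  Returns one
    time x score matrix per arm (arm 0 = RT, arm 1 = TMZ).
    """
    if fit.fitter is None:
        raise ValueError("CoxFit carries no underlying fitter")
    needed = {score_col, arm_col}
    have = {t.split(":")[0] for t in fit.terms.index} | {
        p for t in fit.terms.index for p in t.split(":")
    }
    if not needed <= have:
        raise ValueError(f"fit must include {needed}, has {have}")
    tmax = float(fit.fitter.durations.max())
    time_grid = np.asarray(time_grid, dtype=float)
    if (time_grid > tmax).any():
        warnings.warn("time grid extends beyond observed follow-up; clamping")
        time_grid = np.minimum(time_grid, tmax)
    base = fit.fitter.baseline_survival_
    bt = base.index.to_numpy(dtype=float)
    bs = base.iloc[:, 0].to_numpy(dtype=float)
    # right-continuous step evaluation; S = 1 before the first event time
    idx = np.searchsorted(bt, time_grid, side="right") - 1
    S0 = np.where(idx >= 0, bs[np.maximum(idx, 0)], 1.0)
    out = {}
    for arm_val, arm_name in [(0.0, "RT"), (1.0, "TMZ")]:
        X = pd.DataFrame({score_col: np.asarray(score_grid, float),
                          arm_col: arm_val})
        ph = fit.fitter.predict_partial_hazard(X).to_numpy(dtype=float)
        sf = pd.DataFrame(
            S0[:, None] ** ph[None, :],
            index=pd.Index(time_grid, name="time"),
            columns=[f"score={v:g}" for v in np.asarray(score_grid, float)],
        )
        out[arm_name] = sf
    return out
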