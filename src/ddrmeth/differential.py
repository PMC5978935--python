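"""Moderated-t differential methylation / expression with effect-size gates.

The two-group test follows the empirical-Bayes variance-moderation scheme of
limma's moderated t: per-feature pooled sample variances are shrunk toward a
prior variance s0^2 with prior degrees of freedom d0, both estimated by the
method of moments on the log sample variances; the moderated t statistic
uses the posterior variance and d + d0 degrees of freedom.

Methylation tests run on the M scale; the per-probe effect size reported for
gating is the difference of group mean *betas* (delta_beta), combining the
variance-stabilised test with an interpretable methylation-fraction effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from sample variances.

    Uses the distribution of log sample variances: e = log(s2) - digamma(df/2)
    + log(df/2) has mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2) over trigamma(df/2).  Returns d0 = inf (complete
    shrinkage) when the observed spread does not exceed the sampling spread.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_bar))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(
    M: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    beta: pd.DataFrame | None = None,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t test per feature (features = columns).

    ``groups`` must have exactly two levels with >= 2 samples each.  The
    difference reported is level2 - level1 in sorted-level order.  When
    ``beta`` is given, ``delta_beta`` is the corresponding difference of
    group mean betas; otherwise it is the M-scale difference (useful for
    expression, where the column is the log2 fold change).

    ``prior_df``/``prior_var`` override the estimated hyperparameters
    (``prior_df=0`` reduces to the ordinary pooled-variance t test).
    """
    groups = pd.Series(np.asarray(groups), index=M.index)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected 2 group levels, got {levels}")
    g1, g2 = (groups == levels[0]).to_numpy(), (groups == levels[1]).to_numpy()
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 samples")

    X = M.to_numpy(dtype=float)
    m1, m2 = X[g1].mean(axis=0), X[g2].mean(axis=0)
    diff = m2 - m1
    df_resid = n1 + n2 - 2
    ss = ((X[g1] - m1) ** 2).sum(axis=0) + ((X[g2] - m2) ** 2).sum(axis=0)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, df_resid)
    else:
        d0 = prior_df
        s0_2 = prior_var if prior_var is not None else 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    # zero variance with equal means: no evidence either way
    degenerate = (se == 0) & (diff == 0)
    p = np.where(degenerate, 1.0, p)
    t_mod = np.where(degenerate, 0.0, t_mod)
    p = np.where((se == 0) & (diff != 0), 0.0, p)

    q = multipletests(p, method="fdr_bh")[1]
    if beta is not None:
        B = beta.to_numpy(dtype=float)
        delta_beta = B[g2].mean(axis=0) - B[g1].mean(axis=0)
    else:
        delta_beta = diff
    return pd.DataFrame(
        {
            "diff_M": diff,
            "delta_beta": delta_beta,
            "s2": s2,
            "s2_post": s2_post,
            "d0": d0,
            "s0_2": s0_2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "q": q,
        },
        index=M.columns,
    )


def call_dmps(
    res: pd.DataFrame, delta_beta_min: float = 0.1, q_max: float = 0.1
) -> list[str]:
    """Differentially methylated positions: |delta_beta| >= gate and q <= gate
    (both boundaries inclusive)."""
    mask = (res["delta_beta"].abs() >= delta_beta_min) & (res["q"] <= q_max)
    return list(res.index[mask])


def intersect_dmps(
    sets: list[list[str]],
    directions: list[pd.Series] | None = None,
    require_direction: bool = True,
) -> list[str]:
    """Intersection of >= 2 DMP sets, optionally requiring a consistent sign.

    ``directions[k]`` maps probe -> signed effect (delta_beta) in set k.
    With ``require_direction`` a probe must appear in every set *and* carry
    the same effect sign in all of them.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    if directions is not None and require_direction:
        keep = []
        for probe in common:
            signs = {np.sign(d.loc[probe]) for d in directions}
            if len(signs) == 1 and 0 not in signs:
                keep.append(probe)
        common = set(keep)
    return sorted(common)


def differential_expression(
    expr: pd.DataFrame,
    groups,
    log2fc_min: float = np.log2(1.2),
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Moderated-t differential expression on log-scale values.

    A gene is DE when |log2 fold change| >= log2(1.2) and q <= 0.1, both
    inclusive; ``direction`` labels up-/down-regulation in the second
    (sorted) group level.
    """
    res = moderated_t(expr, groups)
    res = res.rename(columns={"diff_M": "log2fc"}).drop(columns=["delta_beta"])
    res["de"] = (res["log2fc"].abs() >= log2fc_min) & (res["q"] <= q_max)
    res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
    return res
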