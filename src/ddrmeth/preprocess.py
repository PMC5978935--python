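"""Value transforms, probe filtering and empirical-Bayes batch adjustment.

These are the steps applied before every downstream analysis: conversion
between methylation fractions (beta) and the variance-stabilised M scale,
removal of unreliable probes (failed detection, sex chromosomes, SNP
overlap), and ComBat-style location/scale batch correction on M values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import MethylSet

DEFAULT_EPS = 1e-6


def beta_to_m(beta, eps: float = DEFAULT_EPS):
    """logit2 transform: M = log2(beta / (1 - beta)), with clipping at eps.

    Accepts scalars, arrays or DataFrames and preserves the container type.
    """
    arr = np.asarray(beta, dtype=float) if not isinstance(beta, pd.DataFrame) else beta.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite beta values")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1.0 - eps)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (exact on the clipped range)."""
    arr = np.asarray(m, dtype=float) if not isinstance(m, pd.DataFrame) else m.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite M values")
    b = 1.0 / (1.0 + np.power(2.0, -arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(b)
    return b


def filter_probes(
    ms: MethylSet,
    ann: pd.DataFrame,
    det_p_max: float = 0.01,
    max_fail_fraction: float = 0.0,
) -> tuple[MethylSet, pd.DataFrame]:
    """Remove unreliable probes and return (filtered set, removal log).

    A probe is removed when its detection p exceeds ``det_p_max`` in more
    than ``max_fail_fraction`` of samples (default 0: any failing sample
    drops the probe), when it lies on a sex chromosome, or when it overlaps
    a SNP.  The log lists one row per (probe, reason); a probe failing
    several criteria appears under each reason but is removed once.
    """
    probes = ms.beta.columns
    unknown = probes.difference(ann.index)
    if len(unknown) > 0:
        raise KeyError(f"probe {unknown[0]!r} absent from annotation")
    sub = ann.loc[probes]

    reasons: list[tuple[str, str]] = []
    if ms.detection_p is not None:
        fail_frac = (ms.detection_p.to_numpy() > det_p_max).mean(axis=0)
        det_bad = pd.Series(fail_frac > max_fail_fraction, index=probes)
    else:
        det_bad = pd.Series(False, index=probes)
    sex_bad = sub["sex_chrom"].astype(bool)
    snp_bad = sub["snp_flag"].astype(bool)

    for pid in probes[det_bad]:
        reasons.append((pid, "detection_p"))
    for pid in probes[sex_bad.to_numpy()]:
        reasons.append((pid, "sex_chrom"))
    for pid in probes[snp_bad.to_numpy()]:
        reasons.append((pid, "snp"))

    removed = det_bad.to_numpy() | sex_bad.to_numpy() | snp_bad.to_numpy()
    keep = probes[~removed]
    log = pd.DataFrame(reasons, columns=["probe_id", "reason"])
    filtered = MethylSet(
        beta=ms.beta[keep],
        samples=ms.samples,
        detection_p=None if ms.detection_p is None else ms.detection_p[keep],
    )
    return filtered, log


def _trim_var(x: np.ndarray, axis=None, ddof: int = 1) -> np.ndarray:
    return np.var(x, axis=axis, ddof=ddof)


def combat_adjust(
    M: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Parametric empirical-Bayes batch adjustment of an M-value matrix.

    Implements the Johnson–Li–Rabinovic location/scale model: per-probe
    standardisation against the batch-size-weighted grand mean and pooled
    variance, method-of-moments priors (normal for the location effects,
    inverse-gamma for the scale effects), iterative conditional posterior
    estimates, then removal and back-transformation.  Rows are samples.

    Probes with zero pooled variance are passed through unchanged with a
    warning.  Batches must number >= 2, each with >= 2 samples.
    """
    batch = pd.Series(np.asarray(batch), index=M.index)
    levels = batch.unique()
    if len(levels) < 2:
        raise ValueError("combat_adjust requires at least 2 batches")
    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"singleton batch(es): {small}")

    Y = M.to_numpy(dtype=float).T  # probes x samples
    n_probes, n = Y.shape
    B = len(levels)
    batch_onehot = np.stack([(batch == lv).to_numpy(float) for lv in levels], axis=1)  # n x B
    design = batch_onehot
    if covariates is not None:
        C = covariates.loc[M.index].to_numpy(dtype=float)
        design = np.hstack([batch_onehot, C])

    # per-probe least squares for batch means (+ covariate effects)
    XtX = design.T @ design
    beta_hat = np.linalg.solve(XtX, design.T @ Y.T)  # q x probes
    nb = counts.reindex(levels).to_numpy(float)
    grand = (nb / n) @ beta_hat[:B]  # probes
    if covariates is not None:
        cov_part = (design[:, B:] @ beta_hat[B:]).T  # probes x samples
    else:
        cov_part = np.zeros_like(Y)
    stand_mean = grand[:, None] + cov_part

    resid = Y - (design @ beta_hat).T
    var_pooled = (resid**2).mean(axis=1)
    constant = var_pooled <= 1e-12
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant probe(s) passed through unadjusted"
        )
    sd = np.sqrt(np.where(constant, 1.0, var_pooled))
    Z = (Y - stand_mean) / sd[:, None]

    Z_adj = Z.copy()
    for b_idx, lv in enumerate(levels):
        cols = (batch == lv).to_numpy()
        Zb = Z[:, cols]
        n_b = Zb.shape[1]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = _trim_var(Zb, axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        # hyperpriors (method of moments across probes)
        gamma_bar = gamma_hat.mean()
        tau2 = _trim_var(gamma_hat, ddof=1)
        v_bar = delta_hat.mean()
        s2 = _trim_var(delta_hat, ddof=1)
        lam = (v_bar**2 + 2.0 * s2) / s2 if s2 > 0 else 2.0
        theta = (v_bar**3 + v_bar * s2) / s2 if s2 > 0 else v_bar
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (
                n_b * tau2 + delta_star
            )
            ss = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * ss) / (n_b / 2.0 + lam - 1.0)
            change = max(
                np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max()
            )
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        Z_adj[:, cols] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = Z_adj * sd[:, None] + stand_mean
    out[constant] = Y[constant]
    return pd.DataFrame(out.T, index=M.index, columns=M.columns)
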