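"""Probe-state classification in normal brain and functional-CpG selection.

The probe universe is reduced in three steps before any tumor analysis:

1. a three-component univariate Gaussian mixture on per-probe normal-brain
   M values classifies probes as unmethylated (U), hemi-methylated (H) or
   methylated (M); only U probes are kept,
2. probes are restricted to gene promoters (|TSS distance| <= 1500 nt),
   optionally intersected with the DNA-damage-response gene list,
3. a CpG is called *functionally methylated* when its methylation is
   negatively correlated with its gene's expression (Pearson r <= -0.3,
   BH-FDR <= 0.1) in two independent datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STATE_LABELS = np.array(["U", "H", "M"])


@dataclass
class MixtureFit:
    """Result of the three-Gaussian EM fit (components ordered by mean)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    loglik_trace: list[float]
    posterior: pd.DataFrame          # probes x 3
    state: pd.Series                 # per-probe label in {U, H, M}
    n_iter: int = 0
    converged: bool = True
    warnings_: list[str] = field(default_factory=list)


def _em_once(x, means, sds, weights, tol, max_iter, sd_floor=1e-4):
    n = len(x)
    trace = []
    prev = -np.inf
    resp = None
    for it in range(max_iter):
        logcomp = (
            np.log(weights)[None, :]
            + stats.norm.logpdf(x[:, None], means[None, :], sds[None, :])
        )
        lse = np.logaddexp.reduce(logcomp, axis=1)
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logcomp - lse[:, None])
        nk = resp.sum(axis=0)
        if (nk < 1e-8).any():
            return None  # component collapse
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if (sds < sd_floor).any():
            return None
        if ll - prev < tol and it > 0:
            break
        prev = ll
    return means, sds, weights, trace, resp, it + 1


def fit_ntb_mixture(
    ntb_m: pd.Series | np.ndarray,
    n_init: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> MixtureFit:
    """Fit a 3-component univariate Gaussian mixture by EM.

    ``ntb_m`` is the per-probe normal-brain summary (median M across NTB
    samples).  The best of ``n_init`` k-means-seeded starts is kept; runs
    whose components collapse (sd < 1e-4 or empty responsibility) are
    discarded and restarted.  Components are reported in ascending-mean
    order and each probe is assigned the maximum-posterior state
    (lowest mean = U).
    """
    x = np.asarray(ntb_m, dtype=float)
    index = ntb_m.index if isinstance(ntb_m, pd.Series) else pd.RangeIndex(len(x))
    if len(x) < 30:
        raise ValueError("need at least 30 probes to fit the mixture")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in NTB summary")
    rng = np.random.default_rng(seed)

    best = None
    for init in range(n_init):
        if init == 0:
            centers = np.percentile(x, [10, 50, 90]).astype(float)
        else:
            centers = np.sort(rng.choice(x, size=3, replace=False).astype(float))
        if len(np.unique(centers)) < 3:
            centers = centers + rng.normal(0, 1e-3 + x.std() * 1e-3, 3)
        # a few Lloyd iterations to seed means/sds/weights
        for _ in range(10):
            assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
            for k in range(3):
                if (assign == k).any():
                    centers[k] = x[assign == k].mean()
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        means = centers.copy()
        sds = np.array(
            [x[assign == k].std() if (assign == k).sum() > 1 else x.std() / 3
             for k in range(3)]
        )
        sds = np.maximum(sds, 1e-3)
        weights = np.maximum(
            np.array([(assign == k).mean() for k in range(3)]), 1e-3
        )
        weights = weights / weights.sum()
        res = _em_once(x, means, sds, weights, tol, max_iter)
        if res is None:
            continue
        means, sds, weights, trace, resp, n_iter = res
        if best is None or trace[-1] > best[3][-1]:
            best = (means, sds, weights, trace, resp, n_iter)
    if best is None:
        raise RuntimeError("all EM restarts degenerated (component collapse)")

    means, sds, weights, trace, resp, n_iter = best
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    resp = resp[:, order]
    state = STATE_LABELS[np.argmax(resp, axis=1)]

    warns = []
    gaps = np.diff(means)
    if (weights < 0.02).any():
        warns.append("near-empty mixture component (weight < 0.02)")
    if (gaps < 2.0 * sds.min()).any():
        warns.append("poorly separated components; data may have fewer modes")
    for w in warns:
        warnings.warn(w)

    return MixtureFit(
        means=means,
        sds=sds,
        weights=weights,
        loglik=trace[-1],
        loglik_trace=trace,
        posterior=pd.DataFrame(resp, index=index, columns=list(STATE_LABELS)),
        state=pd.Series(state, index=index, name="state"),
        n_iter=n_iter,
        warnings_=warns,
    )


def unmethylated_in_ntb(fit: MixtureFit) -> list[str]:
    """Probes classified as unmethylated (state U) in normal brain."""
    return list(fit.state.index[fit.state == "U"])


def promoter_cpgs(
    ann: pd.DataFrame, window: int = 1500, ddr_only: bool = False
) -> list[str]:
    """Promoter probes with |TSS distance| <= window; optionally DDR genes only."""
    mask = (ann["region_class"] == "promoter") & (
        ann["tss_distance"].abs() <= window
    )
    if ddr_only:
        mask &= ann["ddr_flag"].astype(bool)
    return list(ann.index[mask])


def _dataset_correlations(M: pd.DataFrame, expr: pd.DataFrame,
                          probes: list[str], genes: pd.Series):
    shared = M.index.intersection(expr.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared samples per dataset")
    r = np.full(len(probes), np.nan)
    p = np.full(len(probes), np.nan)
    for i, probe in enumerate(probes):
        gene = genes.loc[probe]
        if gene not in expr.columns:
            continue
        res = stats.pearsonr(M.loc[shared, probe], expr.loc[shared, gene])
        r[i], p[i] = res.statistic, res.pvalue
    q = np.full(len(probes), np.nan)
    testable = ~np.isnan(p)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    return r, p, q


def functional_selection(
    meth1: pd.DataFrame,
    expr1: pd.DataFrame,
    meth2: pd.DataFrame,
    expr2: pd.DataFrame,
    candidates,
    ann: pd.DataFrame,
    r_max: float = -0.3,
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Dual-dataset functional-methylation selection.

    For each candidate promoter probe, the Pearson correlation between its
    M values and its gene's expression is computed within each dataset,
    with a two-sided t test of zero correlation and BH-FDR across the
    testable candidates of that dataset.  A probe is *functional* when
    r <= r_max and q <= q_max in both datasets (boundaries inclusive).
    Candidates whose gene is missing from an expression set are marked
    untestable and excluded from that dataset's FDR denominator.
    """
    candidates = [c for c in candidates]
    missing = [c for c in candidates if c not in ann.index]
    if missing:
        raise KeyError(f"candidate {missing[0]!r} absent from annotation")
    genes = ann.loc[candidates, "gene"]
    r1, p1, q1 = _dataset_correlations(meth1, expr1, candidates, genes)
    r2, p2, q2 = _dataset_correlations(meth2, expr2, candidates, genes)
    functional = (
        (r1 <= r_max) & (q1 <= q_max) & (r2 <= r_max) & (q2 <= q_max)
    )
    functional = np.where(np.isnan(r1) | np.isnan(r2), False, functional)
    return pd.DataFrame(
        {
            "gene": genes.to_numpy(),
            "r1": r1, "p1": p1, "q1": q1,
            "r2": r2, "p2": p2, "q2": q2,
            "functional": functional.astype(bool),
        },
        index=pd.Index(candidates, name="probe_id"),
    )
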