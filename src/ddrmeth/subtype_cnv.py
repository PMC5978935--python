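"""CIMP subtyping and 1p/19q codeletion calling from combined intensities.

Samples are clustered on M values with Ward's criterion (Euclidean
distance), the cluster of higher mean methylation being the CpG island
methylator phenotype (CIMP+).  Copy-number loss is detected from the log2
ratio of combined (methylated + unmethylated) channel intensity against a
reference, segmented by circular binary segmentation (CBS) with a
permutation acceptance rule; an arm is lost when its probe-weighted mean
segment ratio falls below a log2 threshold, and codeletion requires the
simultaneous loss of 1p and 19q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import IntensitySet


def cimp_cluster(
    M: pd.DataFrame, k: int = 2, method: str = "ward", metric: str = "euclidean"
) -> pd.DataFrame:
    """Agglomerative clustering of samples; highest-methylation cluster = CIMP+.

    Returns a DataFrame (index = samples) with integer ``cluster`` labels and
    a boolean ``cimp`` flag marking the cluster of highest mean M value.
    """
    n = len(M)
    if n < 2 and k > 1:
        raise ValueError("need at least 2 samples")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        Z = linkage(M.to_numpy(dtype=float), method=method, metric=metric)
        labels = fcluster(Z, t=k, criterion="maxclust")
    means = pd.Series(M.to_numpy().mean(axis=1), index=M.index).groupby(labels).mean()
    cimp_label = means.idxmax()
    return pd.DataFrame(
        {"cluster": labels, "cimp": labels == cimp_label}, index=M.index
    )


def intensity_logratio(
    its: IntensitySet, reference: list | None = None
) -> pd.DataFrame:
    """Per-probe log2 combined-intensity ratio against a reference.

    ``reference`` is a set of sample ids (e.g. normal brain); when omitted
    the cohort itself serves as reference (per-probe median).  Ratios are
    median-centered within each sample, making them invariant to global
    intensity scaling.
    """
    total = its.total
    ref = total if reference is None else total.loc[reference]
    if len(ref) == 0:
        raise ValueError("empty reference set")
    ref_med = ref.median(axis=0)
    if (ref_med <= 0).any():
        raise ValueError("zero/negative reference median intensity")
    lr = np.log2(total / ref_med)
    return lr.sub(lr.median(axis=1), axis=0)


def _max_arc_stat(x: np.ndarray, grids=None):
    """Maximal two-sample t-like statistic over circular arcs (i, j].

    Returns (stat, (i, j)); None when the segment is too short or flat.
    """
    n = len(x)
    if n < 4:
        return None
    S = np.concatenate([[0.0], np.cumsum(x)])
    SS = np.concatenate([[0.0], np.cumsum(x * x)])
    T, TT = S[-1], SS[-1]
    if grids is None:
        grids = _arc_grids(n)
    I, J, K = grids
    sum_in = S[J] - S[I]
    ss_in = SS[J] - SS[I]
    m = n - K
    mean_in = sum_in / K
    mean_out = (T - sum_in) / m
    resid = (ss_in - K * mean_in**2) + ((TT - ss_in) - m * mean_out**2)
    pv = np.maximum(resid / max(n - 2, 1), 1e-12)
    t = np.abs(mean_in - mean_out) / np.sqrt(pv * (1.0 / K + 1.0 / m))
    best = int(np.argmax(t))
    return float(t[best]), (int(I[best]), int(J[best]))


def _arc_grids(n: int):
    idx = np.arange(n + 1)
    I, J = np.meshgrid(idx, idx, indexing="ij")
    K = J - I
    valid = (K >= 1) & (K <= n - 1)
    return I[valid], J[valid], K[valid].astype(float)


def segment_cbs(
    x, alpha: float = 0.01, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Recursive circular binary segmentation of an ordered signal.

    At each step the arc maximising the inside/outside two-sample statistic
    is a candidate change; it is accepted when its permutation p value
    (within the current segment) is <= alpha, and the segment is split at
    the arc boundaries.  Returns ordered segments as (start, end, n_probes,
    mean) with ``end`` exclusive.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty signal")
    rng = np.random.default_rng(seed)
    breakpoints: set[int] = set()
    grid_cache: dict[int, tuple] = {}

    def grids_for(m):
        if m not in grid_cache:
            grid_cache[m] = _arc_grids(m)
        return grid_cache[m]

    def recurse(s: int, e: int) -> None:
        m = e - s
        if m < 4:
            return
        seg = x[s:e]
        g = grids_for(m)
        res = _max_arc_stat(seg, g)
        if res is None:
            return
        stat, (i, j) = res
        limit = alpha * (1 + n_perm) - 1  # early stop once clearly null
        count = 0
        for _ in range(n_perm):
            st, _ = _max_arc_stat(rng.permutation(seg), g)
            if st >= stat - 1e-12:
                count += 1
                if count > limit:
                    break
        p = (1 + count) / (1 + n_perm)
        if p > alpha:
            return
        pts = sorted({q for q in (s + i, s + j) if s < q < e})
        if not pts:
            return
        for q in pts:
            breakpoints.add(q)
        bounds = [s, *pts, e]
        for a, b in zip(bounds[:-1], bounds[1:]):
            recurse(a, b)

    recurse(0, n)
    bounds = sorted({0, *breakpoints, n})
    rows = [
        (a, b, b - a, float(x[a:b].mean()))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    return pd.DataFrame(rows, columns=["start", "end", "n_probes", "mean"])


@dataclass
class CnaCall:
    """Arm-level copy-number call for one sample."""

    sample_id: str
    arm_means: dict[str, float]
    arm_lost: dict[str, bool]
    codel: bool
    segments: dict[str, pd.DataFrame] = field(default_factory=dict)


def call_codel(
    sample_id: str,
    arm_segments: dict[str, pd.DataFrame],
    loss_threshold: float = -0.2,
    arms: tuple[str, str] = ("1p", "19q"),
) -> CnaCall:
    """Arm lost iff probe-weighted mean segment ratio < threshold; codel iff
    both 1p and 19q are lost."""
    for arm in arms:
        if arm not in arm_segments:
            raise KeyError(f"missing segments for arm {arm!r}")
    arm_means, arm_lost = {}, {}
    for arm, seg in arm_segments.items():
        w = seg["n_probes"].to_numpy(float)
        arm_means[arm] = float(np.average(seg["mean"].to_numpy(float), weights=w))
        arm_lost[arm] = arm_means[arm] < loss_threshold
    codel = bool(arm_lost[arms[0]] and arm_lost[arms[1]])
    return CnaCall(sample_id, arm_means, arm_lost, codel, arm_segments)


def codel_calls(
    its: IntensitySet,
    ann: pd.DataFrame,
    samples: list | None = None,
    reference: list | None = None,
    loss_threshold: float = -0.2,
    alpha: float = 0.01,
    n_perm: int = 200,
    seed: int = 0,
    arms: tuple[str, str] = ("1p", "19q"),
) -> pd.DataFrame:
    """Segment every sample's 1p and 19q log ratios and call codeletion.

    Returns a per-sample table with arm means and the codel flag.  Each
    sample/arm gets a deterministic child seed so calls are reproducible
    and order-independent.
    """
    lr = intensity_logratio(its, reference)
    if samples is None:
        samples = list(lr.index)
    arm_probes = {
        arm: ann[ann["chrom"] == arm].sort_values("pos").index.intersection(lr.columns)
        for arm in arms
    }
    for arm, probes in arm_probes.items():
        if len(probes) < 10:
            raise ValueError(f"need >= 10 probes on arm {arm}, got {len(probes)}")
    rows = []
    for si, sample in enumerate(samples):
        arm_segments = {}
        for ai, arm in enumerate(arms):
            child = int(np.random.SeedSequence([seed, si, ai]).generate_state(1)[0]
                        % (2**31))
            sig = lr.loc[sample, arm_probes[arm]]
            arm_segments[arm] = segment_cbs(
                sig.to_numpy(), alpha=alpha, n_perm=n_perm, seed=child
            )
        call = call_codel(sample, arm_segments, loss_threshold, arms)
        rows.append(
            (sample, call.arm_means[arms[0]], call.arm_means[arms[1]], call.codel)
        )
    return pd.DataFrame(
        rows, columns=["sample_id", f"mean_{arms[0]}", f"mean_{arms[1]}", "codel"]
    ).set_index("sample_id")
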