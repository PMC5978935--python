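"""STATIS: simultaneous analysis of several tables sharing the same variables.

The K tables (one per dataset) share an ordered set of columns (CpG probes)
but may have different samples.  Each table is column-centered and reduced to
its probe-by-probe configuration operator W = X'X, normalised to unit
Hilbert-Schmidt norm so every table contributes unit inertia.  The analysis
then proceeds in three classical steps:

* interstructure - the K x K matrix of RV coefficients between the
  operators is eigendecomposed; the first eigenvector (Perron-Frobenius,
  nonnegative) gives the table weights and its eigenvalue the overall
  agreement, tested by permutation,
* compromise - the weighted average operator C = sum_k alpha_k W_k is
  eigendecomposed into a common reference system for the probes,
* intrastructure - each table's samples are projected onto the compromise
  axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _center(table: pd.DataFrame) -> np.ndarray:
    X = table.to_numpy(dtype=float)
    return X - X.mean(axis=0, keepdims=True)


def crossproduct(table: pd.DataFrame) -> np.ndarray:
    """Column-configuration operator W = X'X / ||X'X||_F (unit HS norm)."""
    Xc = _center(table)
    W = Xc.T @ Xc
    norm = np.linalg.norm(W)
    if norm == 0:
        raise ValueError("zero table: no variance in any column")
    return W / norm


def rv_coefficient(Wx: np.ndarray, Wy: np.ndarray) -> float:
    """RV = <Wx, Wy> / (||Wx|| ||Wy||), in [0, 1] for PSD configurations."""
    nx, ny = np.linalg.norm(Wx), np.linalg.norm(Wy)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm configuration matrix")
    return float(np.sum(Wx * Wy) / (nx * ny))


def _check_tables(tables: list[pd.DataFrame]) -> None:
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    cols = tables[0].columns
    for t in tables[1:]:
        if not t.columns.equals(cols):
            raise ValueError("all tables must share identical ordered columns")


def interstructure(
    tables: list[pd.DataFrame],
) -> tuple[pd.DataFrame, float, np.ndarray]:
    """RV matrix, first eigenvalue and normalised table weights."""
    _check_tables(tables)
    Ws = [crossproduct(t) for t in tables]
    K = len(Ws)
    rv = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            rv[i, j] = rv[j, i] = rv_coefficient(Ws[i], Ws[j])
    lam, vec = np.linalg.eigh(rv)
    lam1 = float(lam[-1])
    w = vec[:, -1]
    if w.sum() < 0:
        w = -w
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    names = [getattr(t, "name", None) or f"table{i + 1}" for i, t in enumerate(tables)]
    return pd.DataFrame(rv, index=names, columns=names), lam1, w


def _lambda1_of_ws(Ws: list[np.ndarray]) -> float:
    K = len(Ws)
    rv = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            rv[i, j] = rv[j, i] = float(
                np.sum(Ws[i] * Ws[j])
            )  # operators already unit-norm
    return float(np.linalg.eigvalsh(rv)[-1])


def permutation_test_interstructure(
    tables: list[pd.DataFrame], B: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutation test of the interstructure's first eigenvalue.

    The null destroys the cross-table column correspondence by permuting the
    column order of each table independently; on the configuration operators
    this is a simultaneous row/column permutation, so the operators are
    computed once.  p = (1 + #{lambda1* >= lambda1}) / (1 + B).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    _check_tables(tables)
    rng = np.random.default_rng(seed)
    Ws = [crossproduct(t) for t in tables]
    lam1 = _lambda1_of_ws(Ws)
    p_cols = Ws[0].shape[0]
    count = 0
    for _ in range(B):
        perm_ws = []
        for W in Ws:
            perm = rng.permutation(p_cols)
            perm_ws.append(W[np.ix_(perm, perm)])
        if _lambda1_of_ws(perm_ws) >= lam1 - 1e-12:
            count += 1
    return (1 + count) / (1 + B), lam1


def compromise_and_projections(
    tables: list[pd.DataFrame], weights: np.ndarray, n_axes: int | None = None
) -> dict:
    """Compromise eigensystem, probe coordinates and per-table projections.

    Returns a dict with ``eigenvalues`` (nonnegative, non-increasing),
    ``column_coords`` (probes x axes, eigenvectors scaled by sqrt of
    eigenvalue) and ``row_coords`` (per-table samples x axes projections of
    the centered, inertia-normalised table onto the compromise axes).
    Tiny negative eigenvalues from round-off are clipped to zero.
    """
    _check_tables(tables)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(tables):
        raise ValueError("one weight per table required")
    Ws = [crossproduct(t) for t in tables]
    C = sum(a * W for a, W in zip(weights, Ws))
    lam, vec = np.linalg.eigh(C)
    lam, vec = lam[::-1], vec[:, ::-1]
    lam = np.where(lam < 0, 0.0, lam)
    if n_axes is None:
        n_axes = min(10, (lam > 1e-12).sum() or 1)
    axes = [f"axis{i + 1}" for i in range(n_axes)]
    probes = tables[0].columns
    col_coords = pd.DataFrame(
        vec[:, :n_axes] * np.sqrt(lam[:n_axes])[None, :], index=probes, columns=axes
    )
    row_coords = []
    for t in tables:
        Xc = _center(t)
        Xc = Xc / np.sqrt(np.linalg.norm(Xc.T @ Xc))
        row_coords.append(
            pd.DataFrame(Xc @ vec[:, :n_axes], index=t.index, columns=axes)
        )
    return {
        "eigenvalues": lam,
        "column_coords": col_coords,
        "row_coords": row_coords,
        "compromise": C,
    }


@dataclass
class StatisResult:
    rv: pd.DataFrame
    lambda1: float
    table_weights: np.ndarray
    compromise_eigenvalues: np.ndarray
    column_coords: pd.DataFrame
    row_coords: list[pd.DataFrame]
    perm_p: float
    B: int
    seed: int


def statis(tables: list[pd.DataFrame], B: int = 999, seed: int = 0) -> StatisResult:
    """Full STATIS run: interstructure + permutation test + compromise."""
    rv, lam1, weights = interstructure(tables)
    perm_p, _ = permutation_test_interstructure(tables, B=B, seed=seed)
    comp = compromise_and_projections(tables, weights)
    return StatisResult(
        rv=rv,
        lambda1=lam1,
        table_weights=weights,
        compromise_eigenvalues=comp["eigenvalues"],
        column_coords=comp["column_coords"],
        row_coords=comp["row_coords"],
        perm_p=perm_p,
        B=B,
        seed=seed,
    )
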