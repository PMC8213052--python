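"""Henderson Method III reductions, variance components, and F-tests.

The association test is built from reductions in sums of squares
R(subset) = y' X (X'X)^- X' y computed with a rank-revealing pivoted QR.
Method III solves variance components from the expected values of
reduction differences along a fixed fitting order
(fixed -> e -> ae -> de -> aae -> ade -> dae -> dde -> residual):

    E[R(step k) - R(step k-1)]
        = sum_g sigma^2_g * [||Q_k' Z_g||_F^2 - ||Q_{k-1}' Z_g||_F^2]
          + sigma^2_eps * (rank_k - rank_{k-1})

which, with sigma^2_eps taken from the full-model SSE, is a small linear
system in the component variances.  Negative method-of-moments estimates are
kept signed here; truncation to zero happens only at heritability reporting.

Every term set is tested against the full-model residual mean square:
F = [R(full) - R(full \\ terms)] / df1 / MSE.  With an empty random part this
is exactly the classical partial F of ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

from .encoding import RANDOM_GROUP_ORDER, DesignBundle

_RANK_TOL_FACTOR = 1e-10


def orthonormal_basis(X: np.ndarray, against: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal basis of col(X) (optionally after projecting out ``against``).

    ``against`` must itself have orthonormal columns.  Rank decided by a
    pivoted QR with tolerance relative to the largest diagonal of R.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    if against is not None and against.shape[1]:
        X = X - against @ (against.T @ X)
        # re-orthogonalize once for numerical safety
        X = X - against @ (against.T @ X)
    Q, R, _ = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return np.empty((X.shape[0], 0))
    tol = diag[0] * max(X.shape) * _RANK_TOL_FACTOR
    rank = int((diag > tol).sum())
    return Q[:, :rank]


def reduction_ss(y: np.ndarray, columns: np.ndarray) -> float:
    """R(subset) = y' X (X'X)^- X' y for the given design columns."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty phenotype vector")
    Q = orthonormal_basis(columns)
    proj = Q.T @ y
    return float(proj @ proj)


@dataclass
class FResult:
    f_value: float
    df1: int
    df2: int
    p_nominal: float
    term_set: list[str] = field(default_factory=list)


@dataclass
class FitResult:
    fixed_estimates: dict[str, float]
    vc: dict[str, float]               # raw (signed) method-of-moments components
    sigma2_eps: float
    reductions: dict[str, float]
    dfs: dict[str, int]

    def vc_truncated(self) -> dict[str, float]:
        return {k: max(v, 0.0) for k, v in self.vc.items()}


def henderson3_components(y: np.ndarray, design: DesignBundle) -> FitResult:
    """Method III variance components for the random-term groups of ``design``."""
    y = np.asarray(y, dtype=float)
    n = y.size
    groups = [g for g in RANDOM_GROUP_ORDER if g in design.random_groups]
    Zs = {g: design.random[:, design.random_groups[g]] for g in groups}

    # sequential orthonormal bases: fixed, then each random group in order
    Q = orthonormal_basis(design.fixed)
    ranks = [Q.shape[1]]
    reductions = {"fixed": float(np.sum((Q.T @ y) ** 2))}
    bases = [Q]
    for g in groups:
        E = orthonormal_basis(Zs[g], against=Q)
        Q = np.hstack([Q, E])
        bases.append(Q)
        ranks.append(Q.shape[1])
        reductions[f"fixed+...+{g}"] = reductions[list(reductions)[-1]] + float(
            np.sum((E.T @ y) ** 2)
        )
    rank_full = ranks[-1]
    if n <= rank_full:
        raise ValueError("n does not exceed the full-model rank")
    r_full = list(reductions.values())[-1]
    sse = float(y @ y) - r_full
    sigma2_eps = sse / (n - rank_full)

    # expectation system: one equation per fitted group
    k = len(groups)
    T = np.zeros((k, k))
    d = np.zeros(k)
    for step in range(k):
        Qp, Qk = bases[step], bases[step + 1]
        d[step] = (
            list(reductions.values())[step + 1]
            - list(reductions.values())[step]
            - sigma2_eps * (ranks[step + 1] - ranks[step])
        )
        for j, g in enumerate(groups):
            Z = Zs[g]
            T[step, j] = np.sum((Qk.T @ Z) ** 2) - np.sum((Qp.T @ Z) ** 2)
    if k:
        try:
            comps = np.linalg.solve(T, d)
        except np.linalg.LinAlgError:
            raise ValueError(
                "singular Method III expectation system; reduce the candidate set"
            ) from None
    else:
        comps = np.empty(0)

    W = design.full_matrix()
    beta, *_ = np.linalg.lstsq(W, y, rcond=None)
    fixed_estimates = dict(zip(design.full_labels, beta))
    return FitResult(
        fixed_estimates=fixed_estimates,
        vc={f"sigma2_{g}": float(c) for g, c in zip(groups, comps)},
        sigma2_eps=sigma2_eps,
        reductions=reductions,
        dfs={"rank_full": rank_full, "df_resid": n - rank_full},
    )


def f_test_terms(y: np.ndarray, design: DesignBundle, term_set: list[str]) -> FResult:
    """Joint F-test of ``term_set`` against the full-model residual mean square."""
    y = np.asarray(y, dtype=float)
    n = y.size
    registry = design.term_registry
    unknown = [t for t in term_set if t not in registry]
    if unknown:
        raise KeyError(f"terms not in design: {unknown}")
    keep = [lab for lab in design.full_labels if lab not in set(term_set)]
    W_full = design.full_matrix()
    Q_red = orthonormal_basis(design.columns_for(keep)) if keep else np.empty((n, 0))
    E = orthonormal_basis(design.columns_for(term_set), against=Q_red)
    df1 = E.shape[1]
    if df1 == 0:
        raise ValueError("tested terms are aliased with the background model")
    rank_full = Q_red.shape[1] + df1
    df2 = n - rank_full
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    extra = float(np.sum((E.T @ y) ** 2))
    r_red = float(np.sum((Q_red.T @ y) ** 2)) if Q_red.shape[1] else 0.0
    sse = float(y @ y) - r_red - extra
    mse = sse / df2
    f = (extra / df1) / mse if mse > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return FResult(f_value=float(f), df1=df1, df2=df2, p_nominal=p, term_set=list(term_set))
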