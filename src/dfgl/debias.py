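"""Bias correction of the fused group Lasso estimate.

Penalized estimates are biased toward zero (and toward fusion), so their
coordinates have no usable sampling distribution.  The one-step
correction subtracts ``M_hat^(g) x (average score)`` from each group's
estimate, where ``M_hat^(g)`` approximately inverts the per-group
information matrix

    Sigma_hat^(g) = n_g^{-1} sum_i ddloss(y_i, x_i' beta_hat^(g)) x_i x_i',

row by row via the quadratic program

    min 1/2 m' Sigma m   s.t.  ||Sigma m - e_j||_max <= mu_g,

with ``mu_g = c sqrt(log p / n_g)`` (default c = 0.7).  The debiased
coordinates admit Gaussian approximations with variances read off
``V_hat^(g) = M_hat Sigma_hat M_hat'``, which feeds the chi-squared test
statistics in :mod:`dfgl.inference`.

The QP is solved through its Lagrangian-dual lasso form
``min 1/2 m' Sigma m - m_j + mu ||m||_1`` by cyclic coordinate descent:
for positive semidefinite Sigma the KKT systems of the two problems
coincide, so a converged coordinate-descent point is QP-optimal and
automatically satisfies the max-norm constraint.  All p rows share Sigma
and are updated simultaneously; a row whose constraint is not met at the
common mu is retried with mu inflated by 1.5 (at most 20 times), and the
mu actually used is recorded per row.  Row solutions are independent
problems, so results do not depend on execution order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data import CoefficientMatrix, GroupedDataset
from .losses import ddloss, dloss

__all__ = [
    "InformationEstimate",
    "DecorrelationMatrix",
    "DebiasedFit",
    "information_estimate",
    "decorrelation_row",
    "decorrelation_matrix",
    "debias_coefficients",
    "debias_pipeline",
]

_FEAS_TOL = 1e-6
_MU_INFLATE = 1.5
_MAX_INFLATE = 20


@dataclass
class InformationEstimate:
    """Per-group information matrices Sigma_hat^(g) (p x p, symmetric PSD)."""

    matrices: list[np.ndarray]


@dataclass
class DecorrelationMatrix:
    """Approximate inverse information for one group.

    Row j of ``M`` solves the constrained QP with target e_j;
    ``mu_used[j]`` records the constraint level actually attained (after
    any inflation) and ``status[j]`` is "ok" or "inflated".
    """

    M: np.ndarray
    mu_used: np.ndarray
    status: list[str]


@dataclass
class DebiasedFit:
    """Debiased coefficients and their variance estimates.

    ``b_hat`` is p x G; ``V_g[g]`` is the p x p matrix
    ``M_hat Sigma_hat M_hat'`` of group g.  ``variance_row(j)`` returns
    the G-vector of entries ``V_hat^(g)_jj / n_g`` — the diagonal of the
    per-feature matrix V_hat_(j).
    """

    b_hat: np.ndarray
    V_g: list[np.ndarray]
    group_sizes: list[int]

    def variance_row(self, j: int) -> np.ndarray:
        return np.array(
            [V[j, j] / n_g for V, n_g in zip(self.V_g, self.group_sizes)]
        )

    @property
    def n_groups(self) -> int:
        return self.b_hat.shape[1]

    @property
    def n_features(self) -> int:
        return self.b_hat.shape[0]


def information_estimate(data: GroupedDataset, B_hat) -> InformationEstimate:
    """Sigma_hat^(g) = n_g^{-1} X' diag(sigma(1-sigma)) X per group."""
    Bv = B_hat.values if isinstance(B_hat, CoefficientMatrix) else np.asarray(B_hat)
    if Bv.shape != (data.n_features, data.n_groups):
        raise ValueError("B_hat shape mismatch")
    mats = []
    for g, (X, y) in enumerate(zip(data.designs, data.responses)):
        nu = X @ Bv[:, g]
        if not np.all(np.isfinite(nu)):
            raise FloatingPointError(f"non-finite linear predictor in group {g}")
        wts = ddloss(y, nu)
        S = (X * wts[:, None]).T @ X / X.shape[0]
        mats.append((S + S.T) / 2.0)
    return InformationEstimate(mats)


def _cd_columns(Sigma, X0, mu, max_sweeps, tol):
    """Coordinate descent on 1/2 x'Sx - x_j + mu_j ||x||_1 per column j.

    Column j of the slab targets e_j; ``mu`` is a per-column vector.
    Returns the solution slab and the sweeps used (== max_sweeps means
    the tolerance was not reached).
    """
    p = Sigma.shape[0]
    X = X0.copy()
    R = Sigma @ X
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for i in range(p):
            sii = Sigma[i, i]
            z = -R[i, :] + sii * X[i, :]
            z[i] += 1.0
            new = np.sign(z) * np.maximum(np.abs(z) - mu, 0.0) / sii
            delta = new - X[i, :]
            nz = np.max(np.abs(delta))
            if nz > 0.0:
                R += np.outer(Sigma[:, i], delta)
                X[i, :] = new
                if nz > max_delta:
                    max_delta = nz
        if max_delta <= tol:
            return X, sweep + 1
    return X, max_sweeps


try:  # pragma: no cover
    from numba import njit

    _cd_columns_jit = njit(cache=True)(_cd_columns)
except Exception:  # pragma: no cover
    _cd_columns_jit = _cd_columns


def _solve_columns(
    Sigma: np.ndarray,
    mu0: float,
    columns: np.ndarray | None = None,
    max_sweeps: int = 20000,
    tol: float = 1e-11,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Solve the QP for the requested target columns with mu inflation.

    Returns ``(X, mu_used, status)`` where column k of X is the solution
    for target index columns[k].
    """
    p = Sigma.shape[0]
    diag = np.diag(Sigma)
    if np.any(diag <= 0):
        raise ValueError("information matrix has a nonpositive diagonal entry")
    if columns is None:
        columns = np.arange(p)
    # solve the full slab; restrict afterwards (columns share all work)
    init = np.diag(1.0 / diag).copy()
    mu_vec = np.full(p, mu0)
    status = ["ok"] * p
    X, _ = _cd_columns_jit(
        np.ascontiguousarray(Sigma), init, mu_vec, max_sweeps, tol
    )
    for _ in range(_MAX_INFLATE):
        if not np.all(np.isfinite(X)):
            bad_cols = np.flatnonzero(~np.all(np.isfinite(X), axis=0))
            X[:, bad_cols] = init[:, bad_cols]
            viol = np.zeros(p, dtype=bool)
            viol[bad_cols] = True
        else:
            resid = Sigma @ X - np.eye(p)
            viol = np.max(np.abs(resid), axis=0) > mu_vec + _FEAS_TOL
        if not np.any(viol):
            break
        for j in np.flatnonzero(viol):
            mu_vec[j] *= _MU_INFLATE
            status[j] = "inflated"
        X, _ = _cd_columns_jit(
            np.ascontiguousarray(Sigma), X, mu_vec, max_sweeps, tol
        )
    else:
        resid = Sigma @ X - np.eye(p)
        still = np.flatnonzero(np.max(np.abs(resid), axis=0) > mu_vec + _FEAS_TOL)
        if still.size and np.isin(columns, still).any():
            raise RuntimeError(
                f"decorrelation QP unsolved for rows {still.tolist()} "
                f"after {_MAX_INFLATE} mu inflations"
            )
    cols = np.asarray(columns)
    return X[:, cols], mu_vec[cols], [status[int(j)] for j in cols]


def decorrelation_row(
    Sigma: np.ndarray,
    j: int,
    mu: float,
    max_sweeps: int = 20000,
    tol: float = 1e-11,
) -> tuple[np.ndarray, float, str]:
    """Solve row j's QP ``min 1/2 m'Sm s.t. ||Sm - e_j||_max <= mu``.

    On infeasibility/solver failure the constraint level is inflated by
    1.5 (at most 20 times).  Returns ``(m_hat_j, mu_used, status)``.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    try:
        X, mu_used, status = _solve_columns(
            Sigma, mu, columns=np.array([j]), max_sweeps=max_sweeps, tol=tol
        )
    except RuntimeError as exc:
        raise RuntimeError(f"decorrelation failed for row {j}: {exc}") from exc
    return X[:, 0], float(mu_used[0]), status[0]


def decorrelation_matrix(
    Sigma_g: np.ndarray,
    n_g: int,
    p: int | None = None,
    c: float = 0.7,
    max_sweeps: int = 20000,
    tol: float = 1e-11,
) -> DecorrelationMatrix:
    """All p rows of M_hat for one group, ``mu_g = c sqrt(log p / n_g)``."""
    Sigma_g = np.asarray(Sigma_g, dtype=float)
    if p is None:
        p = Sigma_g.shape[0]
    if c <= 0:
        raise ValueError("c must be positive")
    mu = c * math.sqrt(math.log(p) / n_g)
    X, mu_used, status = _solve_columns(Sigma_g, mu, max_sweeps=max_sweeps, tol=tol)
    n_inflated = sum(s == "inflated" for s in status)
    if n_inflated:
        warnings.warn(
            f"decorrelation: mu inflated for {n_inflated} of {p} rows "
            f"(max mu used {mu_used.max():.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return DecorrelationMatrix(M=X.T.copy(), mu_used=mu_used, status=status)


def debias_coefficients(
    data: GroupedDataset,
    B_hat,
    M_hats: list[DecorrelationMatrix] | list[np.ndarray],
    info: InformationEstimate | None = None,
) -> DebiasedFit:
    """One-step correction ``b^(g) = beta^(g) - M^(g) (avg score)^(g)``.

    Also assembles ``V_hat^(g) = M Sigma M'`` and checks that every
    per-feature variance ``V^(g)_jj / n_g`` is strictly positive.
    """
    Bv = B_hat.values if isinstance(B_hat, CoefficientMatrix) else np.asarray(B_hat)
    Ms = [M.M if isinstance(M, DecorrelationMatrix) else np.asarray(M) for M in M_hats]
    if info is None:
        info = information_estimate(data, Bv)
    G = data.n_groups
    b_hat = np.empty_like(Bv)
    V_g = []
    for g in range(G):
        X, y = data.designs[g], data.responses[g]
        n_g = X.shape[0]
        nu = X @ Bv[:, g]
        score = X.T @ dloss(y, nu) / n_g
        b_hat[:, g] = Bv[:, g] - Ms[g] @ score
        V = Ms[g] @ info.matrices[g] @ Ms[g].T
        V = (V + V.T) / 2.0
        diag = np.diag(V) / n_g
        if np.any(diag <= 1e-12):
            raise FloatingPointError(
                f"degenerate variance in group {g}: min diag {diag.min():.3g}"
            )
        V_g.append(V)
    return DebiasedFit(b_hat=b_hat, V_g=V_g, group_sizes=data.group_sizes)


def debias_pipeline(data: GroupedDataset, B_hat, c: float = 0.7) -> DebiasedFit:
    """Convenience: information estimate -> M_hat per group -> debiased fit."""
    info = information_estimate(data, B_hat)
    Ms = [
        decorrelation_matrix(info.matrices[g], data.group_sizes[g], c=c)
        for g in range(data.n_groups)
    ]
    return debias_coefficients(data, B_hat, Ms, info=info)
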