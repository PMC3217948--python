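"""Simplex-constrained least squares via active-set quadratic programming.

The mixing model states that a mixed sample's expression vector x is a
convex combination of the pure-type columns of the signature matrix S.
Recovering the mixing weights is the convex QP

    minimize   ||S a - x||_2^2
    subject to sum(a) = 1,  a >= 0,

whose feasible set is the unit simplex. Convexity guarantees that the
active-set iteration below terminates at the global optimum; the solution
is exact (machine precision) on the final working set because each step
solves the equality-constrained KKT system directly.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg

__all__ = ["solve_simplex_lsq", "kkt_residual"]

_MAX_ITER_FACTOR = 50


def _kkt_step(Q: np.ndarray, g: np.ndarray, free: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the equality-constrained subproblem on the free variables.

    Returns the step p over free indices (zero elsewhere) and the
    multiplier of the sum-to-one constraint:

        [ Q_FF  1 ] [ p_F ]   [ -g_F ]
        [ 1^T   0 ] [ lam ] = [  0   ]
    """
    idx = np.flatnonzero(free)
    nf = idx.size
    kkt = np.zeros((nf + 1, nf + 1))
    kkt[:nf, :nf] = Q[np.ix_(idx, idx)]
    kkt[:nf, nf] = 1.0
    kkt[nf, :nf] = 1.0
    rhs = np.zeros(nf + 1)
    rhs[:nf] = -g[idx]
    try:
        sol = scipy.linalg.solve(kkt, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError:
        sol, *_ = scipy.linalg.lstsq(kkt, rhs)
    if not np.all(np.isfinite(sol)):
        sol, *_ = scipy.linalg.lstsq(kkt, rhs)
    p = np.zeros(Q.shape[0])
    p[idx] = sol[:nf]
    return p, float(sol[nf])


def solve_simplex_lsq(
    S: np.ndarray, x: np.ndarray, clip_tol: float = 1e-9
) -> tuple[np.ndarray, float]:
    """Globally minimize ||S a - x||^2 over the unit simplex.

    Parameters
    ----------
    S
        Basis matrix, shape (n_genes, n_types) with n_genes > n_types.
    x
        Mixed expression vector over the same genes.
    clip_tol
        Solver round-off in [-clip_tol, 0) is clipped to 0 and the
        solution renormalized; a more negative entry raises.

    Returns
    -------
    a, residual_norm
        The optimal fractions (row of the mixing matrix) and ||S a - x||_2.
    """
    S = np.asarray(S, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if S.ndim != 2:
        raise ValueError("S must be 2-D")
    m, n = S.shape
    if x.size != m:
        raise ValueError(f"x has length {x.size}, expected {m}")
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite values in S or x")
    if m <= n:
        raise ValueError(f"system must be overdetermined: {m} genes <= {n} types")

    Q = 2.0 * (S.T @ S)
    c = 2.0 * (S.T @ x)
    # collinear columns make Q singular; a relative ridge restores definiteness
    if np.linalg.matrix_rank(S) < n:
        ridge = 1e-10 * float(np.mean(np.diag(Q)))
        warnings.warn(
            "signature columns are collinear; adding a small ridge to the QP",
            stacklevel=2,
        )
        Q = Q + ridge * np.eye(n)

    # normalize the objective so the KKT system mixes O(1) blocks with the
    # unit constraint row (the minimizer is unchanged)
    scale = max(float(np.abs(Q).max()), np.finfo(float).tiny)
    Q = Q / scale
    c = c / scale
    step_tol = 1e-13
    mult_tol = 1e-10

    a = np.full(n, 1.0 / n)  # feasible start: uniform mixture
    working = np.zeros(n, dtype=bool)  # active a_i = 0 bounds

    for _ in range(_MAX_ITER_FACTOR * (n + 1)):
        g = Q @ a - c
        p, lam = _kkt_step(Q, g, ~working)
        if np.max(np.abs(p)) <= step_tol:
            # stationary on working set: check bound multipliers.
            # the KKT step returns lam with g_i = -lam on the free set, so the
            # Lagrange multiplier of an active bound is mu_i = g_i + lam
            mu = g[working] + lam
            if working.sum() == 0 or mu.min() >= -mult_tol:
                break
            release = np.flatnonzero(working)[int(np.argmin(mu))]
            working[release] = False
            continue
        # ratio test against a_i >= 0 for decreasing free variables
        decreasing = (~working) & (p < -step_tol)
        alpha = 1.0
        blocking = -1
        if decreasing.any():
            idx = np.flatnonzero(decreasing)
            ratios = -a[idx] / p[idx]
            j = int(np.argmin(ratios))
            if ratios[j] < alpha:
                alpha = max(ratios[j], 0.0)
                blocking = idx[j]
        a = a + alpha * p
        if blocking >= 0:
            a[blocking] = 0.0
            working[blocking] = True
    else:
        raise RuntimeError("active-set QP did not converge")

    if a.min() < -clip_tol:
        raise RuntimeError(f"QP produced infeasible fraction {a.min():.3e}")
    a = np.clip(a, 0.0, None)
    a = a / a.sum()
    residual = float(np.linalg.norm(S @ a - x))
    return a, residual


def kkt_residual(S: np.ndarray, x: np.ndarray, a: np.ndarray) -> float:
    """Max violation of the KKT conditions at ``a`` (certificate of optimality).

    Checks primal feasibility, stationarity of the free coordinates and
    dual feasibility (non-negative multipliers) of the active bounds, all
    relative to the problem's scale.
    """
    S = np.asarray(S, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    a = np.asarray(a, dtype=float).ravel()
    g = 2.0 * S.T @ (S @ a - x)
    scale = max(float(np.abs(2.0 * S.T @ S).max()), 1.0)
    active = a <= 1e-8
    free = ~active
    res = abs(a.sum() - 1.0)
    res = max(res, float(-min(a.min(), 0.0)))
    if free.any():
        lam = float(np.mean(g[free]))  # stationarity: g_i = lam on free set
        res = max(res, float(np.max(np.abs(g[free] - lam)) / scale))
    else:
        lam = float(g.min())
    if active.any():
        res = max(res, float(max(0.0, -np.min(g[active] - lam)) / scale))
    return res
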