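"""Numba coordinate-descent kernels for L1-penalized least squares.

The objective solved here is the un-normalized form

    f(beta) = ||y - X beta||^2 + lam * sum_j |beta_j|,

so the soft-threshold level for coordinate j is lam / 2 and the update divides
by the column's squared norm.  Residuals are maintained incrementally, giving
O(n p) work per sweep.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True, inline="always")
def _sweep(X, y, r, beta, col_sq, half_lam, idx):
    """One pass of coordinate updates over ``idx``; returns the largest
    absolute coefficient change."""
    n = X.shape[0]
    max_delta = 0.0
    for k in range(idx.shape[0]):
        j = idx[k]
        if col_sq[j] <= 0.0:
            continue
        bj = beta[j]
        zj = bj * col_sq[j]
        for i in range(n):
            zj += X[i, j] * r[i]
        bnew = soft_threshold(zj, half_lam) / col_sq[j]
        d = bnew - bj
        if d != 0.0:
            beta[j] = bnew
            for i in range(n):
                r[i] -= d * X[i, j]
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def cd_solve(X, y, lam, beta, tol, max_iter):
    """Cyclic coordinate descent from warm start ``beta`` (modified in place).

    Returns (n_iter, converged, max_delta_last).  Convergence: the largest
    absolute coefficient change in a full sweep drops below ``tol``.  Between
    full sweeps the active coordinates are iterated to convergence first,
    which only reorders updates and leaves the stopping criterion intact.
    """
    n, p = X.shape
    col_sq = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        col_sq[j] = s
    r = y - X @ beta
    half_lam = 0.5 * lam
    all_idx = np.arange(p)
    it = 0
    max_delta = 0.0
    while it < max_iter:
        it += 1
        max_delta = _sweep(X, y, r, beta, col_sq, half_lam, all_idx)
        if max_delta < tol:
            return it, True, max_delta
        active = np.flatnonzero(beta)
        if active.shape[0] == 0:
            continue
        while it < max_iter:
            it += 1
            inner_delta = _sweep(X, y, r, beta, col_sq, half_lam, active)
            if inner_delta < tol:
                break
    return it, False, max_delta


@njit(cache=True)
def cd_path(X, y, lams, tol, max_iter):
    """Warm-started solutions along a descending lambda sequence.

    Returns (betas (len(lams) x p), n_iters, converged_flags).  ``lams`` must
    be sorted descending for the warm starts to be effective; the caller is
    responsible for ordering and for mapping results back.
    """
    n, p = X.shape
    m = lams.shape[0]
    betas = np.zeros((m, p))
    n_iters = np.zeros(m, dtype=np.int64)
    conv = np.zeros(m, dtype=np.bool_)
    beta = np.zeros(p)
    for k in range(m):
        it, ok, _ = cd_solve(X, y, lams[k], beta, tol, max_iter)
        betas[k] = beta
        n_iters[k] = it
        conv[k] = ok
    return betas, n_iters, conv
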