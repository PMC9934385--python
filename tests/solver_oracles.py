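"""Independent solvers used as oracles in tests.

The weighted-L1 objective ||y - X b||^2 + lam * sum f_j |b_j| becomes a
smooth bound-constrained quadratic program after the positive/negative split
b = u - v with u, v >= 0, which L-BFGS-B solves to high precision.  This
shares no code with the package's coordinate-descent path.
"""

import numpy as np
from scipy.optimize import minimize


def weighted_l1_qp(X, y, lam, factors=None, tol=1e-14):
    """Minimize ||y - Xb||^2 + lam * sum f_j |b_j| via the split-variable QP."""
    n, p = X.shape
    f = np.ones(p) if factors is None else np.asarray(factors, float)

    def fun(z):
        u, v = z[:p], z[p:]
        b = u - v
        r = y - X @ b
        grad_b = -2.0 * X.T @ r
        val = r @ r + lam * np.sum(f * (u + v))
        grad = np.concatenate([grad_b + lam * f, -grad_b + lam * f])
        return val, grad

    res = minimize(fun, np.zeros(2 * p), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * p,
                   options={"ftol": tol, "gtol": 1e-12, "maxiter": 50_000})
    b = res.x[:p] - res.x[p:]
    r = y - X @ b
    return b, float(r @ r + lam * np.sum(f * np.abs(b)))


def check_function_forms(u, tau):
    """The four equivalent closed forms of the quantile check function."""
    ind_le = 1.0 if u <= 0 else 0.0
    ind_gt = 1.0 - ind_le
    return (
        (tau - ind_le) * u,
        ((1 - tau) * ind_le + tau * ind_gt) * abs(u),
        u * (tau * ind_gt - (1 - tau) * ind_le),
        (abs(u) + (2 * tau - 1) * u) / 2.0,
    )
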