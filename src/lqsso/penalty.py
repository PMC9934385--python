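"""Quantile check function and lqsso penalty weights.

The lqsso penalty replaces the lasso's uniform weight on |beta_j| with the
check function of quantile regression evaluated at the sign of an initial
coefficient estimate: coordinate j is charged ``tau`` if the initial estimate
is positive and ``1 - tau`` otherwise.  The quantile level ``tau`` thus acts
as an asymmetry dial: tau = 0.5 recovers the lasso (up to a factor of 2),
while tau near 0 or 1 penalizes one sign class almost for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "EPS_WEIGHT",
    "InitialEstimates",
    "PenaltySpec",
    "check_function",
    "compute_weights",
    "penalty_value",
]

#: Lower clamp for penalty weights.  tau in {0, 1} gives one sign class a zero
#: weight, which would break the rescaling x_j / w_j**q; clamped coordinates
#: are effectively unpenalized.
EPS_WEIGHT = 1e-8


@dataclass(frozen=True)
class InitialEstimates:
    """Initial coefficient estimates whose signs drive the lqsso weights."""

    beta: NDArray[np.float64]
    source: str = "user"  # {"ols", "ridge", "user"}

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim != 1:
            raise ValueError("initial estimates must be a 1-d vector")
        if not np.all(np.isfinite(beta)):
            raise ValueError("initial estimates must be finite")
        object.__setattr__(self, "beta", beta)

    @property
    def p(self) -> int:
        return self.beta.shape[0]


@dataclass(frozen=True)
class PenaltySpec:
    """A realized lqsso penalty: quantile level, exponent, weights, strength.

    ``lam`` is the penalty strength on the scale of the fitting objective
    RSS(beta) + lam * sum_j w_j**q |beta_j| (no 1/n factor).
    """

    tau: float
    weights: NDArray[np.float64]
    lam: float = 0.0
    q: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if self.lam < 0:
            raise ValueError(f"lambda must be nonnegative, got {self.lam}")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be a finite nonnegative vector")
        object.__setattr__(self, "weights", w)

    @property
    def p(self) -> int:
        return self.weights.shape[0]


def check_function(u: ArrayLike, tau: float) -> NDArray[np.float64] | float:
    """Quantile check function rho_tau(u) = [tau - I(u <= 0)] * u.

    Always nonnegative; rho_tau(u) = tau*u for u > 0 and (1-tau)*|u| for
    u <= 0.  Vectorized over ``u``.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    u_arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u_arr)):
        raise ValueError("check_function requires finite input")
    out = (tau - (u_arr <= 0)) * u_arr
    # exact zero at u=0 regardless of sign convention
    return out if out.ndim else float(out)


def compute_weights(
    init: InitialEstimates | ArrayLike,
    tau: float,
    eps: float = EPS_WEIGHT,
) -> NDArray[np.float64]:
    """Lqsso weights from the signs of initial estimates.

    w_j = tau if the initial estimate is strictly positive, else (1 - tau),
    clamped below at ``eps`` so downstream column rescaling stays finite.
    Only the signs of the initial estimates matter.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    beta = init.beta if isinstance(init, InitialEstimates) else np.asarray(init, float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("initial estimates must be finite")
    w = np.where(beta > 0, tau, 1.0 - tau)
    return np.maximum(w, eps)


def penalty_value(beta: ArrayLike, spec: PenaltySpec) -> float:
    """Penalty term lam * sum_j w_j**q * |beta_j|."""
    b = np.asarray(beta, dtype=float)
    if b.shape != spec.weights.shape:
        raise ValueError(
            f"beta has length {b.shape}, penalty weights have length "
            f"{spec.weights.shape}"
        )
    return float(spec.lam * np.sum(spec.weights**spec.q * np.abs(b)))
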