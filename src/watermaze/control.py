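"""LQR and complexity-constrained (beta-regularized) LQR solvers.

Gain convention used throughout the package: a stored feedback gain ``K``
acts as ``u = -K (x - x_bar)``.  Continuous-time gains are
``K = R^{-1}(B'S + N')`` with ``S`` the stabilizing solution of the algebraic
Riccati equation; discrete gains are ``K = (B'SB + R)^{-1}(B'SA + N')``.

The inverse-optimal-control construction ``cost_from_gain`` builds weights
(Q, R, N) = (K'K, I, K') for which an observed stabilizing gain is exactly
optimal: the running cost becomes the perfect square |K e + u|^2, the Riccati
solution is S = 0, and the accumulated cost vanishes identically along the
closed loop.

The complexity-constrained controller trades the LQR value against the KL
divergence between controlled and free state transitions.  Because both
transition laws are Gaussian with common covariance, the trade-off at weight
``beta`` reduces to a standard LQR with an inflated control penalty
``R_beta = R_dt + (B_dt' Sigma_dt^{-1} B_dt) / beta``: at beta -> 0 control is
infinitely expensive (the naive policy), at beta -> inf the ordinary LQR is
recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_are, solve_discrete_are

from .model import ContinuousModel, CostMatrices, DiscreteModel

__all__ = [
    "CostMatrices",
    "FeedbackGain",
    "ParamGain",
    "RiccatiSolution",
    "BetaPolicy",
    "solve_care",
    "feedback_gain_continuous",
    "solve_dare",
    "discrete_gain",
    "cost_from_gain",
    "expand_param_gain",
    "beta_policy",
]

#: beta above this is treated as the pure LQR (no regularization term).
BETA_LQR_CUTOFF = 1e12

_RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class FeedbackGain:
    """A 2x4 state-feedback gain; u = -K (x - x_bar)."""

    K: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.K).shape != (2, 4):
            raise ValueError("K must be 2x4")

    def controls(self, states: np.ndarray, target: np.ndarray) -> np.ndarray:
        """Feedback controls for an (n, 4) array of states."""
        err = np.atleast_2d(states) - target
        return -err @ self.K.T


@dataclass(frozen=True)
class ParamGain:
    """Three-parameter gain: radial pull K_r, velocity rotation (K_t, K_alpha).

    Expands to
        [[K_r, 0,   K_t cos a, -K_t sin a],
         [0,   K_r, K_t sin a,  K_t cos a]]
    i.e. a restoring force toward the platform plus a rotation of the
    velocity vector by angle K_alpha scaled by K_t.
    """

    K_r: float
    K_t: float
    K_alpha: float


@dataclass(frozen=True)
class RiccatiSolution:
    """Symmetric PSD solution of an algebraic Riccati equation."""

    S: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        if self.S.shape != (4, 4):
            raise ValueError("S must be 4x4")


@dataclass(frozen=True)
class BetaPolicy:
    """Complexity-constrained feedback controller at trade-off weight beta."""

    beta: float
    K: np.ndarray
    R_beta: np.ndarray | None = None
    S: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def controls(self, states: np.ndarray, target: np.ndarray) -> np.ndarray:
        err = np.atleast_2d(states) - target
        return -err @ self.K.T


def _care_residual(A, B, Q, R, N, S) -> float:
    G = np.linalg.solve(R, B.T @ S + N.T)
    res = A.T @ S + S @ A - (S @ B + N) @ G + Q
    return float(np.abs(res).max())


def _dare_residual(A, B, Q, R, N, S) -> float:
    G = np.linalg.solve(B.T @ S @ B + R, B.T @ S @ A + N.T)
    res = A.T @ S @ A - S - (A.T @ S @ B + N) @ G + Q
    return float(np.abs(res).max())


def solve_care(model: ContinuousModel, cost: CostMatrices) -> RiccatiSolution:
    """Stabilizing solution of the continuous algebraic Riccati equation

        A'S + SA - (SB + N) R^{-1} (B'S + N') + Q = 0.
    """
    try:
        S = solve_continuous_are(model.A, model.B, cost.Q, cost.R, s=cost.N)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - solver internals
        raise RuntimeError(f"continuous Riccati solver failed: {exc}") from exc
    S = 0.5 * (S + S.T)
    res = _care_residual(model.A, model.B, cost.Q, cost.R, cost.N, S)
    if res > _RESIDUAL_TOL * max(1.0, float(np.abs(S).max())):
        raise RuntimeError(f"continuous Riccati residual too large: {res:g}")
    return RiccatiSolution(S=S, residual=res)


def feedback_gain_continuous(
    model: ContinuousModel, cost: CostMatrices, sol: RiccatiSolution
) -> FeedbackGain:
    """Gain K = R^{-1}(B'S + N'), applied as u = -K (x - x_bar)."""
    K = np.linalg.solve(cost.R, model.B.T @ sol.S + cost.N.T)
    return FeedbackGain(K=K)


def solve_dare(dmodel: DiscreteModel, dcost: CostMatrices) -> RiccatiSolution:
    """Stabilizing solution of the discrete algebraic Riccati equation.

    Falls back to the backward value recursion (fixed point from S=0) if the
    structured solver fails; non-convergence raises with the residual.
    """
    A, B = dmodel.A_dt, dmodel.B_dt
    Q, R, N = dcost.Q, dcost.R, dcost.N
    S = None
    try:
        S = solve_discrete_are(A, B, Q, R, s=N)
        S = 0.5 * (S + S.T)
    except np.linalg.LinAlgError:
        S = None
    if S is None or not np.isfinite(S).all():
        S = np.zeros((4, 4))
        for _ in range(100_000):
            G = np.linalg.solve(B.T @ S @ B + R, B.T @ S @ A + N.T)
            S_next = A.T @ S @ A - (A.T @ S @ B + N) @ G + Q
            S_next = 0.5 * (S_next + S_next.T)
            if np.abs(S_next - S).max() < 1e-10:
                S = S_next
                break
            S = S_next
    res = _dare_residual(A, B, Q, R, N, S)
    if res > _RESIDUAL_TOL * max(1.0, float(np.abs(S).max())):
        raise RuntimeError(f"discrete Riccati residual too large: {res:g}")
    return RiccatiSolution(S=S, residual=res)


def discrete_gain(
    dmodel: DiscreteModel, dcost: CostMatrices, sol: RiccatiSolution
) -> FeedbackGain:
    """Discrete gain K = (B'SB + R)^{-1}(B'SA + N'); u = -K (x - x_bar)."""
    A, B = dmodel.A_dt, dmodel.B_dt
    K = np.linalg.solve(B.T @ sol.S @ B + dcost.R, B.T @ sol.S @ A + dcost.N.T)
    return FeedbackGain(K=K)


def cost_from_gain(gain: FeedbackGain) -> CostMatrices:
    """Inverse optimal control: weights for which ``gain`` is exactly optimal.

    Returns Q = K'K, R = I, N = K'.  The running cost is then the perfect
    square |K e + u|^2, minimized pointwise by u = -K e, so S = 0 solves both
    the continuous and the discrete Riccati equation, the recovered gain is K
    itself, and the accumulated cost is identically zero along the noiseless
    closed loop.
    """
    K = gain.K
    return CostMatrices(Q=K.T @ K, R=np.eye(2), N=K.T)


def expand_param_gain(pg: ParamGain) -> FeedbackGain:
    """Expand (K_r, K_t, K_alpha) to the structured 2x4 gain."""
    c = pg.K_t * np.cos(pg.K_alpha)
    s = pg.K_t * np.sin(pg.K_alpha)
    K = np.array(
        [
            [pg.K_r, 0.0, c, -s],
            [0.0, pg.K_r, s, c],
        ]
    )
    return FeedbackGain(K=K)


def beta_regularized_R(dmodel: DiscreteModel, dcost: CostMatrices, beta: float) -> np.ndarray:
    """R_beta = R_dt + (B_dt' Sigma_dt^{-1} B_dt) / beta."""
    if beta <= 0:
        raise ValueError("beta must be positive for a finite regularizer")
    info = dmodel.B_dt.T @ np.linalg.solve(dmodel.Sigma_dt, dmodel.B_dt)
    info = 0.5 * (info + info.T)
    return dcost.R + info / beta


def beta_policy(dmodel: DiscreteModel, dcost: CostMatrices, beta: float) -> BetaPolicy:
    """Complexity-constrained optimal controller at trade-off weight beta.

    beta = 0 short-circuits to the zero (naive) policy, since the control
    penalty is infinite there; beta above ``BETA_LQR_CUTOFF`` is treated as
    the unregularized LQR.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if beta == 0:
        return BetaPolicy(beta=0.0, K=np.zeros((2, 4)))
    if beta >= BETA_LQR_CUTOFF:
        sol = solve_dare(dmodel, dcost)
        K = discrete_gain(dmodel, dcost, sol).K
        return BetaPolicy(beta=beta, K=K, R_beta=dcost.R, S=sol.S)
    R_beta = beta_regularized_R(dmodel, dcost, beta)
    reg_cost = CostMatrices(Q=dcost.Q, R=R_beta, N=dcost.N)
    sol = solve_dare(dmodel, reg_cost)
    K = discrete_gain(dmodel, reg_cost, sol).K
    return BetaPolicy(beta=beta, K=K, R_beta=R_beta, S=sol.S)
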