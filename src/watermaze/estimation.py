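"""Maximum-likelihood fitting of the swimming model from trajectory data.

Three stages, mirroring the study design the synthetic cohorts emulate:

1.  ``fit_free_model`` — the oscillator parameters (k, gamma, sigma_q,
    sigma_p) from each animal's first trial, via the Gaussian likelihood of
    the one-step residuals ``eps_t = x_{t+1} - A_dt x_t``.
2.  ``fit_gain_nonparametric`` / ``fit_gain_parametric`` — the feedback gain
    from each animal's last trial, with the dynamics and noise frozen at the
    stage-1 estimates.  The controlled residual is
    ``eps*_t = x_{t+1} - A_dt x_t + B_dt K (x_t - x_bar)``.
    The nonparametric 2x4 gain has a quadratic likelihood and is solved in
    closed form (generalized least squares); the 3-parameter structured gain
    (K_r, K_t, K_alpha) is fitted by multi-start Nelder-Mead.
3.  ``fit_beta`` — a per-animal trade-off weight schedule from the remaining
    trials, grouped by training day; log beta is modelled as a quadratic
    function of day.

Log-likelihoods are reported per transition (normalized), so values are
comparable across data sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from .control import (
    BetaPolicy,
    FeedbackGain,
    ParamGain,
    beta_policy,
    expand_param_gain,
)
from .metrics import estimate_velocities
from .model import (
    CostMatrices,
    DiscreteModel,
    FreeModelParams,
    Trajectory,
    build_continuous_model,
    discretize_dynamics,
)

__all__ = [
    "FitResult",
    "BetaSchedule",
    "free_model_loglik",
    "fit_free_model",
    "gain_loglik",
    "fit_gain_nonparametric",
    "fit_gain_parametric",
    "fit_beta",
    "split_cohort",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: beta profile search grid: log10(beta) in [-3, 4], step 0.1.
BETA_LOG10_GRID = np.round(np.arange(-3.0, 4.0 + 1e-9, 0.1), 10)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: object
    loglik: float  # per-transition average log-likelihood
    n_obs: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


@dataclass
class BetaSchedule:
    """Per-animal quadratic schedule log beta(day) = b0 + b1 day + b2 day^2."""

    mouse_id: str
    b0: float
    b1: float
    b2: float
    beta_by_day: dict[int, float]
    per_day_profile: dict[int, float] = field(default_factory=dict)
    loglik: float = float("nan")
    converged: bool = True

    def beta(self, day: int) -> float:
        return math.exp(self.b0 + self.b1 * day + self.b2 * day * day)


def _ensure_states(trajs: Iterable[Trajectory], smooth_window: int = 3) -> list[np.ndarray]:
    """State arrays for each trajectory, estimating velocities when absent."""
    out = []
    for tr in trajs:
        if tr.velocities is None:
            tr = estimate_velocities(tr, smooth_window=smooth_window)
        out.append(tr.states())
    return out


def split_cohort(
    trials: Sequence[Trajectory],
) -> tuple[list[Trajectory], list[Trajectory], dict[str, dict[int, list[Trajectory]]]]:
    """Partition a cohort by the estimation protocol.

    Returns (first_trials, last_trials, rest_by_mouse_day): each animal's
    first trial of day 1 trains the free model, its last trial of the final
    day trains the gain, and everything else — grouped by (animal, day) —
    trains the beta schedules.
    """
    by_mouse: dict[str, list[Trajectory]] = {}
    for tr in trials:
        by_mouse.setdefault(tr.mouse_id, []).append(tr)
    first, last = [], []
    rest: dict[str, dict[int, list[Trajectory]]] = {}
    for mouse_id, trs in by_mouse.items():
        trs = sorted(trs, key=lambda t: (t.day, t.trial_idx))
        first.append(trs[0])
        last.append(trs[-1])
        mid = trs[1:-1]
        rest[mouse_id] = {}
        for tr in mid:
            rest[mouse_id].setdefault(tr.day, []).append(tr)
    return first, last, rest


# ---------------------------------------------------------------------------
# Stage 1: free model
# ---------------------------------------------------------------------------

def _free_nll(states: Sequence[np.ndarray], params: FreeModelParams, dt: float) -> tuple[float, int]:
    dmodel = discretize_dynamics(build_continuous_model(params), dt)
    cf = cho_factor(dmodel.Sigma_dt)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    nll = 0.0
    n_obs = 0
    for X in states:
        eps = X[1:] - X[:-1] @ dmodel.A_dt.T
        sol = cho_solve(cf, eps.T)
        nll += 0.5 * float(np.einsum("it,ti->", sol, eps))
        n_obs += len(eps)
    nll += 0.5 * n_obs * (logdet + 4.0 * _LOG_2PI)
    return nll, n_obs


def free_model_loglik(
    trajs: Iterable[Trajectory], params: FreeModelParams, dt: float = 0.2
) -> tuple[float, int]:
    """(per-transition log-likelihood, transition count) of the free model."""
    states = _ensure_states(trajs)
    nll, n_obs = _free_nll(states, params, dt)
    return -nll / n_obs, n_obs


def fit_free_model(
    first_trials: Iterable[Trajectory],
    dt: float = 0.2,
    m: float = 20.0,
    tank_radius: float = 60.0,
    n_starts: int = 8,
) -> FitResult:
    """MLE of (k, gamma, sigma_q, sigma_p) with the mass fixed.

    Multi-start Nelder-Mead in log-parameter space, seeded from a coarse
    (k, gamma) grid with moment-matched noise scales.  Diagnostics report
    the damping ratio zeta, the damped angular frequency omega (rad/s) and
    the implied orbital speed at the wall (cm/s).
    """
    states = _ensure_states(first_trials)
    if not states:
        raise ValueError("no trajectories to fit")

    def nll_of(theta: np.ndarray) -> float:
        try:
            p = FreeModelParams(
                k=math.exp(theta[0]), gamma=math.exp(theta[1]), m=m,
                sigma_q=math.exp(theta[2]), sigma_p=math.exp(theta[3]),
            )
            return _free_nll(states, p, dt)[0]
        except (ValueError, np.linalg.LinAlgError, OverflowError):
            return float("inf")

    # moment-based noise inits from residuals at a mid-grid (k, gamma)
    def sigma_init(k0: float, g0: float) -> tuple[float, float]:
        dm = discretize_dynamics(
            build_continuous_model(FreeModelParams(k=k0, gamma=g0, m=m)), dt
        )
        eps = np.vstack([X[1:] - X[:-1] @ dm.A_dt.T for X in states])
        var_q = eps[:, :2].var()
        var_p = eps[:, 2:].var()
        sp = math.sqrt(max(var_p / dt, 1e-8))
        sq = math.sqrt(max((var_q - sp**2 * dt**3 / 3.0) / dt, 1e-8))
        return sq, sp

    k_grid = [1.0, 3.0, 6.0, 12.0]
    g_grid = [0.15, 1.0]
    starts = []
    for k0 in k_grid:
        for g0 in g_grid:
            sq, sp = sigma_init(k0, g0)
            starts.append(np.log([k0, g0, sq, sp]))
    starts = starts[:n_starts]

    best = None
    for x0 in starts:
        res = minimize(
            nll_of, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = FreeModelParams(
        k=math.exp(best.x[0]), gamma=math.exp(best.x[1]), m=m,
        sigma_q=math.exp(best.x[2]), sigma_p=math.exp(best.x[3]),
    )
    nll, n_obs = _free_nll(states, params, dt)
    return FitResult(
        params=params,
        loglik=-nll / n_obs,
        n_obs=n_obs,
        converged=bool(best.success),
        diagnostics={
            "zeta": params.damping_ratio,
            "omega": params.angular_frequency,
            "wall_speed": params.wall_speed(tank_radius),
        },
    )


# ---------------------------------------------------------------------------
# Stage 2: feedback gain
# ---------------------------------------------------------------------------

class _GainStats:
    """Sufficient statistics of the controlled-residual likelihood.

    With y_t = x_{t+1} - A_dt x_t and e_t = x_t - x_bar, the model is
    y_t = -B_dt K e_t + xi_t, so the negative log-likelihood is, up to the
    normalization constant, the quadratic
    1/2 [Syy + 2 <K, G1> + tr(K' M K See)] with M = B' Sigma^{-1} B.
    """

    def __init__(self, states_list: Sequence[np.ndarray], dmodel: DiscreteModel, target: np.ndarray):
        cf = cho_factor(dmodel.Sigma_dt)
        self.logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        Sinv_B = cho_solve(cf, dmodel.B_dt)
        self.M = dmodel.B_dt.T @ Sinv_B
        self.Syy = 0.0
        self.G1 = np.zeros((2, 4))
        self.See = np.zeros((4, 4))
        self.Sye = np.zeros((4, 4))
        self.n_obs = 0
        for X in states_list:
            y = X[1:] - X[:-1] @ dmodel.A_dt.T
            e = X[:-1] - target
            sol = cho_solve(cf, y.T)
            self.Syy += float(np.einsum("it,ti->", sol, y))
            self.G1 += Sinv_B.T @ (y.T @ e)
            self.See += e.T @ e
            self.Sye += y.T @ e
            self.n_obs += len(y)
        self._BtSinv = Sinv_B.T

    def quad(self, K: np.ndarray) -> float:
        return (
            self.Syy
            + 2.0 * float(np.sum(K * self.G1))
            + float(np.trace(K.T @ self.M @ K @ self.See))
        )

    def nll(self, K: np.ndarray) -> float:
        return 0.5 * self.quad(K) + 0.5 * self.n_obs * (self.logdet + 4.0 * _LOG_2PI)

    def gls_gain(self) -> np.ndarray:
        """Closed-form minimizer of the quadratic: the exact MLE of K."""
        return -np.linalg.solve(self.M, self._BtSinv @ self.Sye) @ np.linalg.inv(self.See)


def gain_loglik(
    trajs: Iterable[Trajectory],
    dmodel: DiscreteModel,
    K: np.ndarray,
    target: np.ndarray,
) -> tuple[float, int]:
    """(per-transition log-likelihood, transition count) under gain K."""
    stats = _GainStats(_ensure_states(trajs), dmodel, target)
    return -stats.nll(K) / stats.n_obs, stats.n_obs


def fit_gain_nonparametric(
    last_trials: Iterable[Trajectory],
    dmodel: DiscreteModel,
    target: np.ndarray,
) -> FitResult:
    """Unconstrained 2x4 gain MLE (closed-form generalized least squares)."""
    stats = _GainStats(_ensure_states(last_trials), dmodel, target)
    K = stats.gls_gain()
    return FitResult(
        params=FeedbackGain(K=K),
        loglik=-stats.nll(K) / stats.n_obs,
        n_obs=stats.n_obs,
        converged=True,
    )


def _extract_param_gain(K: np.ndarray) -> ParamGain:
    """Project an unstructured gain onto the (K_r, K_t, K_alpha) structure."""
    K_r = 0.5 * (K[0, 0] + K[1, 1])
    c = 0.5 * (K[0, 2] + K[1, 3])
    s = 0.5 * (K[1, 2] - K[0, 3])
    return ParamGain(K_r=K_r, K_t=float(np.hypot(c, s)), K_alpha=float(np.arctan2(s, c)))


def fit_gain_parametric(
    last_trials: Iterable[Trajectory],
    dmodel: DiscreteModel,
    target: np.ndarray,
    n_starts: int = 8,
) -> FitResult:
    """MLE of the structured gain (K_r, K_t, K_alpha) by multi-start search.

    Starts are the projection of the closed-form unstructured MLE plus
    perturbations of the rotation angle and gain scales.
    """
    stats = _GainStats(_ensure_states(last_trials), dmodel, target)
    pg0 = _extract_param_gain(stats.gls_gain())

    def nll_of(theta: np.ndarray) -> float:
        K = expand_param_gain(ParamGain(*theta)).K
        return stats.nll(K)

    rng = np.random.default_rng(0)
    starts = [np.array([pg0.K_r, pg0.K_t, pg0.K_alpha])]
    for da in (-1.0, 1.0, -0.4, 0.4):
        starts.append(np.array([pg0.K_r, pg0.K_t, pg0.K_alpha + da]))
    while len(starts) < n_starts:
        scale = rng.uniform(0.5, 1.5, size=3)
        starts.append(starts[0] * scale)

    best = None
    for x0 in starts[:n_starts]:
        res = minimize(
            nll_of, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    pg = ParamGain(*best.x)
    if pg.K_t < 0:  # canonical form: K_t >= 0
        pg = ParamGain(pg.K_r, -pg.K_t, math.remainder(pg.K_alpha + math.pi, 2 * math.pi))
    K = expand_param_gain(pg).K
    return FitResult(
        params=pg,
        loglik=-stats.nll(K) / stats.n_obs,
        n_obs=stats.n_obs,
        converged=bool(best.success),
        diagnostics={"K": K, "Kr_over_Kt": pg.K_r / pg.K_t if pg.K_t else float("inf")},
    )


# ---------------------------------------------------------------------------
# Stage 3: beta schedules
# ---------------------------------------------------------------------------

class _BetaGainCache:
    """Memoized beta -> feedback gain for one (dynamics, cost) pair."""

    def __init__(self, dmodel: DiscreteModel, dcost: CostMatrices):
        self.dmodel = dmodel
        self.dcost = dcost
        self._cache: dict[float, np.ndarray] = {}

    def K(self, beta: float) -> np.ndarray:
        key = float(beta)
        if key not in self._cache:
            self._cache[key] = beta_policy(self.dmodel, self.dcost, key).K
        return self._cache[key]


def _profile_beta(stats: _GainStats, cache: _BetaGainCache) -> float:
    """Profile-likelihood estimate of beta on the log10 grid, then refined."""
    grid = BETA_LOG10_GRID
    nlls = np.array([stats.nll(cache.K(10.0**g)) for g in grid])
    i = int(np.argmin(nlls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        return 10.0 ** grid[i]
    res = minimize_scalar(
        lambda g: stats.nll(cache.K(10.0**g)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return 10.0 ** float(res.x)


def fit_beta(
    trials_by_mouse_day: Mapping[str, Mapping[int, Sequence[Trajectory]]],
    dmodel: DiscreteModel,
    dcost: CostMatrices,
    target: np.ndarray,
    mode: str = "joint",
    days: Sequence[int] = (1, 2, 3, 4),
) -> dict[str, BetaSchedule]:
    """Per-animal beta schedules from day-grouped trials.

    ``mode='per-day'`` profiles beta independently for each day and fits the
    quadratic by least squares on log beta; ``mode='joint'`` (default) then
    refines (b0, b1, b2) against the joint likelihood over the animal's days.
    Animals with fewer than 3 usable days fall back to a linear (or constant)
    schedule, with a warning.
    """
    if mode not in ("joint", "per-day"):
        raise ValueError("mode must be 'joint' or 'per-day'")
    cache = _BetaGainCache(dmodel, dcost)
    out: dict[str, BetaSchedule] = {}
    for mouse_id, by_day in trials_by_mouse_day.items():
        day_stats: dict[int, _GainStats] = {}
        for day, trajs in by_day.items():
            trajs = list(trajs)
            if trajs:
                day_stats[day] = _GainStats(_ensure_states(trajs), dmodel, target)
        if not day_stats:
            continue
        profile = {d: _profile_beta(st, cache) for d, st in day_stats.items()}
        used_days = sorted(profile)
        logb = np.log([profile[d] for d in used_days])
        degree = 2
        if len(used_days) < 3:
            warnings.warn(
                f"{mouse_id}: only {len(used_days)} usable day(s); "
                "reducing the beta schedule to degree "
                f"{max(len(used_days) - 1, 0)}"
            )
            degree = max(len(used_days) - 1, 0)
        d_arr = np.array(used_days, dtype=float)
        V = np.vander(d_arr, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, logb, rcond=None)
        b = np.zeros(3)
        b[: degree + 1] = coef
        converged = True

        if mode == "joint" and len(used_days) >= 2:
            def joint_nll(bvec: np.ndarray) -> float:
                total = 0.0
                for d, st in day_stats.items():
                    lb = bvec[0] + bvec[1] * d + bvec[2] * d * d
                    lb = min(max(lb, -20.0), 20.0)
                    total += st.nll(cache.K(math.exp(lb)))
                return total

            free_idx = list(range(degree + 1))

            def wrapped(theta: np.ndarray) -> float:
                bvec = np.zeros(3)
                bvec[free_idx] = theta
                return joint_nll(bvec)

            res = minimize(
                wrapped, b[free_idx], method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500},
            )
            b = np.zeros(3)
            b[free_idx] = res.x
            converged = bool(res.success)

        sched = BetaSchedule(
            mouse_id=mouse_id,
            b0=float(b[0]), b1=float(b[1]), b2=float(b[2]),
            beta_by_day={},
            per_day_profile=profile,
            converged=converged,
        )
        sched.beta_by_day = {d: sched.beta(d) for d in days}
        total_nll = sum(
            st.nll(cache.K(sched.beta(d))) for d, st in day_stats.items()
        )
        total_n = sum(st.n_obs for st in day_stats.values())
        sched.loglik = -total_nll / total_n
        out[mouse_id] = sched
    return out
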