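"""Trajectory simulation and theoretical value-complexity frontiers.

Free (uncontrolled), LQR, and beta-constrained trials are rolled out from
the sampled dynamics ``x' = A_dt x + B_dt u + xi``.  Trials stop at the first
sample on the platform or at the 60 s cap (300 steps at dt = 0.2 s).

The value-complexity curve is the optimal trade-off frontier: for each beta
on a logarithmic grid the beta-constrained controller is simulated repeatedly
from a release state and the mean value and mean complexity are recorded.
For each complexity level the curve gives the maximal expected value
achievable at that complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .control import BetaPolicy, beta_policy
from .metrics import trajectory_cost_value, trajectory_complexity
from .model import CostMatrices, DiscreteModel, TankGeometry, Trajectory

__all__ = [
    "VCCurve",
    "FrontierGrid",
    "simulate_trajectory",
    "simulate_ensemble",
    "value_complexity_curve",
]

#: 60 s trial cap at dt = 0.2 s.
DEFAULT_MAX_STEPS = 300


@dataclass(frozen=True)
class FrontierGrid:
    """Configuration of the frontier sweep (log-spaced beta grid)."""

    beta_min: float = 1e-5
    beta_max: float = 1e5
    n_beta: int = 50
    n_reps: int = 1000
    max_steps: int = DEFAULT_MAX_STEPS
    log_spacing: bool = True
    seed: int = 0

    def betas(self) -> np.ndarray:
        if self.log_spacing:
            return np.logspace(
                np.log10(self.beta_min), np.log10(self.beta_max), self.n_beta
            )
        return np.linspace(self.beta_min, self.beta_max, self.n_beta)


@dataclass
class VCCurve:
    """Monte-Carlo estimate of one release point's value-complexity frontier."""

    release: str
    betas: np.ndarray
    mean_value: np.ndarray
    mean_complexity: np.ndarray
    se_value: np.ndarray
    se_complexity: np.ndarray
    n_reps: int
    seed: int


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def simulate_trajectory(
    dmodel: DiscreteModel,
    policy: BetaPolicy | None,
    x0: np.ndarray,
    geometry: TankGeometry,
    max_steps: int = DEFAULT_MAX_STEPS,
    seed: int | np.random.Generator = 0,
    clamp_boundary: bool = False,
    noise: bool = True,
    control_gate: np.ndarray | None = None,
    velocity_brake: np.ndarray | None = None,
    stop_at_platform: bool = True,
    **trajectory_meta,
) -> tuple[Trajectory, np.ndarray]:
    """Roll out one trial; returns the trajectory and its controls.

    The trial stops at the first sample on the platform or after
    ``max_steps`` transitions.  With ``clamp_boundary`` positions are
    projected radially onto the tank and the outward radial velocity is
    zeroed — a visualization device only, never used in fitting or frontier
    computation (the free model itself imposes no wall).  ``control_gate``
    optionally scales the control per step and ``velocity_brake`` scales the
    velocity after each step — together they implement injected flotation
    episodes (a floating animal stops thrusting and rapidly loses speed,
    faster than the swimming-fitted damping alone would predict).
    """
    x0 = np.asarray(x0, dtype=float)
    if np.linalg.norm(x0[:2]) > geometry.radius + 1e-9:
        raise ValueError("initial position outside the tank")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = geometry.target_state
    L = dmodel.noise_chol if noise else None
    states = [x0.copy()]
    controls = []
    x = x0.copy()
    for t in range(max_steps):
        u = np.zeros(2) if policy is None else -policy.K @ (x - target)
        if control_gate is not None and t < len(control_gate):
            u = u * control_gate[t]
        x = dmodel.A_dt @ x + dmodel.B_dt @ u
        if L is not None:
            x = x + L @ rng.standard_normal(4)
        if velocity_brake is not None and t < len(velocity_brake):
            x[2:] *= velocity_brake[t]
        if clamp_boundary:
            r = np.linalg.norm(x[:2])
            if r > geometry.radius:
                unit = x[:2] / r
                x[:2] = unit * geometry.radius
                v_rad = x[2:] @ unit
                if v_rad > 0:
                    x[2:] = x[2:] - v_rad * unit
        controls.append(u)
        states.append(x.copy())
        if stop_at_platform and geometry.on_platform(x[:2])[0]:
            break
    arr = np.array(states)
    traj = Trajectory(
        positions=arr[:, :2],
        velocities=arr[:, 2:],
        dt=dmodel.dt,
        **trajectory_meta,
    )
    return traj, np.array(controls)


def simulate_ensemble(
    dmodel: DiscreteModel,
    dcost: CostMatrices,
    K: np.ndarray,
    x0: np.ndarray,
    geometry: TankGeometry,
    n_reps: int,
    max_steps: int = DEFAULT_MAX_STEPS,
    seed: int = 0,
    seed_key: tuple[int, ...] = (),
    stop_at_platform: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rollout of n_reps trials under gain K from a common start.

    Returns per-repetition (value, complexity).  With ``stop_at_platform``
    (trial semantics) accumulation stops for a repetition once it reaches the
    platform; otherwise the horizon is fixed at ``max_steps``.  Noise streams
    are derived per (seed_key, rep) so any single repetition is reproducible
    in isolation.
    """
    target = geometry.target_state
    L = dmodel.noise_chol
    eps = np.empty((n_reps, max_steps, 4))
    for r in range(n_reps):
        rng = _child_rng(seed, *seed_key, r)
        eps[r] = rng.standard_normal((max_steps, 4))
    eps = eps @ L.T

    X = np.tile(np.asarray(x0, dtype=float), (n_reps, 1))
    cost = np.zeros(n_reps)
    info = np.zeros(n_reps)
    alive = np.ones(n_reps, dtype=bool)
    Sinv_B = np.linalg.solve(dmodel.Sigma_dt, dmodel.B_dt)
    M_info = dmodel.B_dt.T @ Sinv_B  # u' M u = per-step KL * 2
    for t in range(max_steps):
        if not alive.any():
            break
        E = X[alive] - target
        U = -E @ K.T
        cost[alive] += 0.5 * (
            np.einsum("ri,ij,rj->r", E, dcost.Q, E)
            + np.einsum("ri,ij,rj->r", U, dcost.R, U)
            + 2.0 * np.einsum("ri,ij,rj->r", E, dcost.N, U)
        )
        info[alive] += 0.5 * np.einsum("ri,ij,rj->r", U, M_info, U)
        X[alive] = X[alive] @ dmodel.A_dt.T + U @ dmodel.B_dt.T + eps[alive, t]
        if stop_at_platform:
            hit = np.zeros(n_reps, dtype=bool)
            hit[alive] = geometry.on_platform(X[alive, :2])
            alive &= ~hit
    return -cost, info


def value_complexity_curve(
    dmodel: DiscreteModel,
    dcost: CostMatrices,
    release_states: dict[str, np.ndarray],
    geometry: TankGeometry,
    grid: FrontierGrid | None = None,
) -> dict[str, VCCurve]:
    """Value-complexity frontier per release point.

    For each beta on the grid the beta-constrained controller is built and
    ``n_reps`` trials are simulated from the release state (zero initial
    velocity); their mean value and complexity give one frontier point.
    Solver failures at a grid point are recorded as NaN, not fatal.
    """
    grid = grid or FrontierGrid()
    betas = grid.betas()
    curves: dict[str, VCCurve] = {}
    policies: list[BetaPolicy | None] = []
    for b in betas:
        try:
            policies.append(beta_policy(dmodel, dcost, float(b)))
        except (RuntimeError, np.linalg.LinAlgError):
            policies.append(None)
    for ri, (release, x0) in enumerate(release_states.items()):
        mv = np.full(len(betas), np.nan)
        mc = np.full(len(betas), np.nan)
        sv = np.full(len(betas), np.nan)
        sc = np.full(len(betas), np.nan)
        for bi, pol in enumerate(policies):
            if pol is None:
                continue
            vals, infos = simulate_ensemble(
                dmodel,
                dcost,
                pol.K,
                x0,
                geometry,
                n_reps=grid.n_reps,
                max_steps=grid.max_steps,
                seed=grid.seed,
                seed_key=(ri, bi),
            )
            mv[bi] = vals.mean()
            mc[bi] = infos.mean()
            sv[bi] = vals.std(ddof=1) / np.sqrt(grid.n_reps)
            sc[bi] = infos.std(ddof=1) / np.sqrt(grid.n_reps)
        curves[release] = VCCurve(
            release=release,
            betas=betas.copy(),
            mean_value=mv,
            mean_complexity=mc,
            se_value=sv,
            se_complexity=sc,
            n_reps=grid.n_reps,
            seed=grid.seed,
        )
    return curves
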