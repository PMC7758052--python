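"""Per-trial value, complexity, free energy, and classical maze measures.

Value is the negative accumulated quadratic cost of a trial; complexity is
the summed KL divergence between the controlled and the free (naive)
state-transition distributions along the path.  With common Gaussian noise
the per-step KL reduces to ``1/2 u' B_dt' Sigma_dt^{-1} B_dt u`` (nats) — by
the large-deviations (Sanov) argument, the exponential rate at which a naive
animal would fail to reproduce the controlled behavior.  Free energy combines
the two at trade-off weight beta: F = I - beta * V.

Classical measures (latency to platform, path length, mean speed, trial-mean
distance to the platform / Gallagher index, flotation episodes) operate on
the raw sampled path.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .control import BetaPolicy
from .model import CostMatrices, DiscreteModel, TankGeometry, Trajectory

__all__ = [
    "TrialMetrics",
    "estimate_velocities",
    "trajectory_cost_value",
    "trajectory_complexity",
    "empirical_policy_controls",
    "performance_measures",
    "floating_episodes",
    "free_energy",
]


@dataclass(frozen=True)
class TrialMetrics:
    """All per-trial quantities; value <= 0, complexity >= 0 (nats)."""

    value: float
    complexity: float
    free_energy: float
    latency: float
    path_length: float
    mean_speed: float
    gallagher: float
    n_float_episodes: int

    def as_dict(self) -> dict:
        return asdict(self)


def estimate_velocities(traj: Trajectory, smooth_window: int = 3) -> Trajectory:
    """Finite-difference velocities with moving-average smoothing.

    Central differences on interior samples, one-sided at the ends, then a
    moving average of width ``smooth_window`` (edge-truncated).  Deterministic;
    numerical differentiation of sampled positions amplifies noise, which the
    smoothing partly suppresses.
    """
    q = traj.positions
    if len(q) < 3:
        raise ValueError("need at least 3 samples to estimate velocities")
    v = np.gradient(q, traj.dt, axis=0)
    if smooth_window > 1:
        w = int(smooth_window)
        kernel = np.ones(w)
        smoothed = np.empty_like(v)
        counts = np.convolve(np.ones(len(v)), kernel, mode="same")
        for c in range(v.shape[1]):
            smoothed[:, c] = np.convolve(v[:, c], kernel, mode="same") / counts
        v = smoothed
    return traj.with_velocities(v)


def _quadratic_step_costs(
    states: np.ndarray,
    controls: np.ndarray,
    dcost: CostMatrices,
    target: np.ndarray,
) -> np.ndarray:
    err = states - target
    sq = np.einsum("ti,ij,tj->t", err, dcost.Q, err)
    su = np.einsum("ti,ij,tj->t", controls, dcost.R, controls)
    sx = 2.0 * np.einsum("ti,ij,tj->t", err, dcost.N, controls)
    return 0.5 * (sq + su + sx)


def trajectory_cost_value(
    traj: Trajectory,
    dmodel: DiscreteModel,
    dcost: CostMatrices,
    controls: np.ndarray,
    target: np.ndarray,
) -> tuple[float, float]:
    """Accumulated quadratic cost and its negative (the value) for one trial.

    ``controls`` holds one control vector per transition (length n-1); the
    sum runs over the transitions of the trial.
    """
    states = traj.states()
    controls = np.atleast_2d(controls)
    if len(controls) != len(states) - 1:
        raise ValueError(
            f"controls ({len(controls)}) must align with transitions ({len(states) - 1})"
        )
    cost = float(_quadratic_step_costs(states[:-1], controls, dcost, target).sum())
    return cost, -cost


def trajectory_complexity(controls: np.ndarray, dmodel: DiscreteModel) -> float:
    """Summed per-step KL divergence (nats) of controlled vs free transitions.

    Each step contributes 1/2 u' B_dt' Sigma_dt^{-1} B_dt u; zero controls
    give exactly zero complexity.
    """
    controls = np.atleast_2d(controls)
    try:
        Bu = np.linalg.solve(
            dmodel.Sigma_dt, (controls @ dmodel.B_dt.T).T
        ).T
    except np.linalg.LinAlgError as exc:
        raise ValueError("Sigma_dt is singular; complexity undefined") from exc
    per_step = 0.5 * np.einsum("ti,ti->t", controls @ dmodel.B_dt.T, Bu)
    return float(per_step.sum())


def empirical_policy_controls(
    traj: Trajectory, policy: BetaPolicy, target: np.ndarray
) -> np.ndarray:
    """Policy-implied controls u_t = -K_beta (x_t - x_bar) at observed states.

    These are the controls attributed to the animal given its fitted
    trade-off weight; they feed the value and complexity computations for
    empirical trials.  One control per transition (the last sample emits
    none).
    """
    states = traj.states()
    return policy.controls(states[:-1], target)


def performance_measures(
    traj: Trajectory, geometry: TankGeometry
) -> tuple[float, float, float, float]:
    """(latency, path_length, mean_speed, gallagher) for one trial.

    Latency is the time of the first sample on the platform (trial duration
    if never reached); path length sums the segment lengths; mean speed is
    path length over duration; the Gallagher index is the sample-mean
    distance to the platform center.
    """
    q = traj.positions
    on = geometry.on_platform(q)
    hits = np.flatnonzero(on)
    latency = hits[0] * traj.dt if len(hits) else traj.duration
    seg = np.linalg.norm(np.diff(q, axis=0), axis=1)
    path_length = float(seg.sum())
    mean_speed = path_length / traj.duration if traj.duration > 0 else 0.0
    gallagher = float(
        np.linalg.norm(q - geometry.platform_center, axis=1).mean()
    )
    return float(latency), path_length, float(mean_speed), gallagher


def floating_episodes(
    traj: Trajectory, frac: float = 0.1
) -> tuple[int, list[tuple[int, int]]]:
    """Flotation episodes: maximal runs of samples slower than frac x mean speed.

    Speed is the instantaneous velocity magnitude; the threshold is ``frac``
    (default 1/10) of the trial-mean speed.  A single slow sample counts as
    an episode.  Returns the episode count and [start, end) index spans.
    """
    if traj.velocities is None:
        raise ValueError("velocities required; run estimate_velocities first")
    speed = np.linalg.norm(traj.velocities, axis=1)
    thresh = frac * speed.mean()
    slow = speed < thresh
    spans: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], slow.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        spans.append((int(start), int(stop)))
    return len(spans), spans


def free_energy(value: float, complexity: float, beta: float) -> float:
    """F = complexity - beta * value (nats); beta must be non-negative."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return complexity - beta * value


def trial_metrics(
    traj: Trajectory,
    dmodel: DiscreteModel,
    dcost: CostMatrices,
    policy: BetaPolicy,
    geometry: TankGeometry,
    float_frac: float = 0.1,
) -> TrialMetrics:
    """Assemble the full metric set for one velocity-bearing trial."""
    target = geometry.target_state
    controls = empirical_policy_controls(traj, policy, target)
    cost, value = trajectory_cost_value(traj, dmodel, dcost, controls, target)
    complexity = trajectory_complexity(controls, dmodel)
    latency, path_length, mean_speed, gallagher = performance_measures(traj, geometry)
    n_float, _ = floating_episodes(traj, frac=float_frac)
    return TrialMetrics(
        value=value,
        complexity=complexity,
        free_energy=free_energy(value, complexity, policy.beta),
        latency=latency,
        path_length=path_length,
        mean_speed=mean_speed,
        gallagher=gallagher,
        n_float_episodes=n_float,
    )
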