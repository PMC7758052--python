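"""Tank geometry, continuous-time swimming dynamics, and exact discretization.

The naive (uncontrolled) mouse is modelled as a 2-D stochastic damped harmonic
oscillator: a central restoring force of strength ``k`` produces the
quasi-circular wall-hugging (thigmotactic) paths of untrained animals, a
damping term ``gamma`` models water viscosity, and isotropic additive Gaussian
noise drives the trajectories outward.  The state is
``x = [q_x, q_y, p_x, p_y]`` (position in cm, velocity in cm/s), evolving as

    dx/dt = A x + B u + xi(t),      xi ~ N(0, Sigma_xi)

where ``u`` is the steering control exerted by a trained animal.  The control
enters the velocity rows of the state as an acceleration (cm/s^2); all fitted
feedback gains in this package are expressed in those units.

Discretization is exact under a zero-order hold at the tracking interval
``dt`` (0.2 s for the study design emulated here): the sampled dynamics,
process-noise covariance and quadratic cost weights are computed with
augmented matrix exponentials (Van Loan blocks), which remain valid when ``A``
is singular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.linalg import expm

__all__ = [
    "TankGeometry",
    "FreeModelParams",
    "ContinuousModel",
    "DiscreteModel",
    "CostMatrices",
    "Trajectory",
    "build_continuous_model",
    "discretize_dynamics",
    "discretize_cost",
]

#: Tracking interval of the emulated study design (s).
DEFAULT_DT = 0.2

#: Trial cap (s): an animal not reaching the platform is removed after 60 s.
TRIAL_CAP_S = 60.0


def _polar(radius: float, angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([radius * math.cos(a), radius * math.sin(a)])


@dataclass(frozen=True)
class TankGeometry:
    """Circular tank with a fixed escape platform in the NW quadrant.

    Coordinates: origin at the tank center, x east, y north, units cm.
    Release points sit near the wall (radius 55 cm by default); the platform
    center is in the middle of the NW quadrant at polar (30 cm, 135 deg).
    """

    radius: float = 60.0
    platform_center: np.ndarray = field(
        default_factory=lambda: _polar(30.0, 135.0)
    )
    platform_radius: float = 5.0
    release_points: Mapping[str, np.ndarray] = field(
        default_factory=lambda: {
            "E": _polar(55.0, 0.0),
            "S": _polar(55.0, -90.0),
            "NE": _polar(55.0, 45.0),
            "SW": _polar(55.0, -135.0),
        }
    )

    def __post_init__(self) -> None:
        if np.linalg.norm(self.platform_center) + self.platform_radius >= self.radius:
            raise ValueError("platform must lie strictly inside the tank")
        for label, pt in self.release_points.items():
            if np.linalg.norm(pt) > self.radius + 1e-9:
                raise ValueError(f"release point {label!r} lies outside the tank")

    @property
    def target_state(self) -> np.ndarray:
        """Target state x_bar: at rest on the platform center."""
        return np.array([*self.platform_center, 0.0, 0.0])

    def on_platform(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of position samples within the platform disc."""
        positions = np.atleast_2d(positions)
        d = np.linalg.norm(positions - self.platform_center, axis=-1)
        return d <= self.platform_radius


@dataclass(frozen=True)
class FreeModelParams:
    """Parameters of the naive-swimming (uncontrolled) model.

    k
        restoring-force constant toward the tank center; k/m is the squared
        angular frequency of the orbit (1/s^2 after division by the mass).
    gamma
        damping constant; gamma/m is the velocity decay rate (1/s).
    m
        body mass (g), fixed at 20 g for a typical mouse.
    sigma_q, sigma_p
        position- and velocity-noise scales (cm/s and cm/s^2 per sqrt(s)):
        the continuous noise covariance is diag(sigma_q^2, ..., sigma_p^2).
    """

    k: float = 3.7
    gamma: float = 0.47
    m: float = 20.0
    sigma_q: float = 1.1
    sigma_p: float = 4.5

    def __post_init__(self) -> None:
        for name in ("k", "gamma", "m", "sigma_q", "sigma_p"):
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be positive")

    # -- derived oscillator diagnostics ------------------------------------
    @property
    def damping_ratio(self) -> float:
        """zeta = gamma / (2 sqrt(m k)); < 1 means underdamped."""
        return self.gamma / (2.0 * math.sqrt(self.m * self.k))

    @property
    def natural_frequency(self) -> float:
        """Undamped angular frequency omega_0 = sqrt(k/m), rad/s."""
        return math.sqrt(self.k / self.m)

    @property
    def angular_frequency(self) -> float:
        """Damped angular frequency omega = omega_0 sqrt(1 - zeta^2), rad/s."""
        z = self.damping_ratio
        return self.natural_frequency * math.sqrt(max(0.0, 1.0 - z * z))

    def wall_speed(self, radius: float = 60.0) -> float:
        """Orbital speed omega * r (cm/s) of the oscillator near the wall."""
        return self.angular_frequency * radius


@dataclass(frozen=True)
class ContinuousModel:
    """Continuous-time linear dynamics (A, B) and noise covariance Sigma_xi."""

    A: np.ndarray
    B: np.ndarray
    Sigma_xi: np.ndarray
    params: FreeModelParams | None = None

    def __post_init__(self) -> None:
        if self.A.shape != (4, 4) or self.B.shape != (4, 2):
            raise ValueError("A must be 4x4 and B 4x2")
        if self.Sigma_xi.shape != (4, 4):
            raise ValueError("Sigma_xi must be 4x4")


@dataclass(frozen=True)
class DiscreteModel:
    """Sampled dynamics at step dt: x' = A_dt x + B_dt u + xi, xi~N(0, Sigma_dt)."""

    A_dt: np.ndarray
    B_dt: np.ndarray
    Sigma_dt: np.ndarray
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        sym_err = np.abs(self.Sigma_dt - self.Sigma_dt.T).max()
        if sym_err > 1e-10:
            raise ValueError("Sigma_dt must be symmetric")
        if np.linalg.eigvalsh(self.Sigma_dt).min() <= 0:
            raise ValueError("Sigma_dt must be positive definite")

    @property
    def noise_chol(self) -> np.ndarray:
        return np.linalg.cholesky(self.Sigma_dt)


@dataclass(frozen=True)
class CostMatrices:
    """Quadratic trajectory-cost weights.

    The accumulated cost of a path x_t with controls u_t relative to the
    target state x_bar is

        J = 1/2 sum_t [ e_t' Q e_t + u_t' R u_t + 2 e_t' N u_t ],
        e_t = x_t - x_bar,

    with Q PSD (state error), R PD (control effort) and N the cross term.
    The terminal weight is identically zero: failing to be on the platform
    when the trial is capped carries no extra penalty.
    """

    Q: np.ndarray
    R: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        if self.Q.shape != (4, 4) or self.R.shape != (2, 2) or self.N.shape != (4, 2):
            raise ValueError("Q must be 4x4, R 2x2, N 4x2")
        if np.abs(self.Q - self.Q.T).max() > 1e-10 or np.abs(self.R - self.R.T).max() > 1e-10:
            raise ValueError("Q and R must be symmetric")
        if np.linalg.eigvalsh(self.R).min() <= 0:
            raise ValueError("R must be positive definite")
        if np.linalg.eigvalsh(self.Q).min() < -1e-10:
            raise ValueError("Q must be positive semidefinite")

    def stacked(self) -> np.ndarray:
        """The composite 6x6 weight [[Q, N], [N', R]]."""
        top = np.hstack([self.Q, self.N])
        bot = np.hstack([self.N.T, self.R])
        return np.vstack([top, bot])


@dataclass
class Trajectory:
    """One trial: sampled positions (and optionally velocities) plus metadata."""

    positions: np.ndarray
    dt: float = DEFAULT_DT
    velocities: np.ndarray | None = None
    mouse_id: str = ""
    genotype: str = "WT"
    sex: str = "M"
    day: int = 1
    trial_idx: int = 1
    release: str = "E"
    excluded: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.positions) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def duration(self) -> float:
        """Trial duration (s), one step per transition."""
        return (len(self.positions) - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.dt

    def states(self) -> np.ndarray:
        """Stacked (n, 4) state samples [q_x, q_y, p_x, p_y]; needs velocities."""
        if self.velocities is None:
            raise ValueError("trajectory has no velocities; run estimate_velocities")
        return np.hstack([self.positions, self.velocities])

    def with_velocities(self, velocities: np.ndarray) -> "Trajectory":
        out = replace(self)
        out.velocities = np.asarray(velocities, dtype=float)
        return out


def build_continuous_model(params: FreeModelParams) -> ContinuousModel:
    """Assemble (A, B, Sigma_xi) from the oscillator parameters.

    A couples position to velocity and applies the restoring force -k/m and
    damping -gamma/m isotropically; B routes the two control components into
    the velocity rows as accelerations; Sigma_xi is diagonal with the
    position/velocity noise variances.
    """
    k_m = params.k / params.m
    g_m = params.gamma / params.m
    A = np.zeros((4, 4))
    A[0, 2] = A[1, 3] = 1.0
    A[2, 0] = A[3, 1] = -k_m
    A[2, 2] = A[3, 3] = -g_m
    B = np.zeros((4, 2))
    B[2, 0] = B[3, 1] = 1.0
    Sigma_xi = np.diag(
        [params.sigma_q**2, params.sigma_q**2, params.sigma_p**2, params.sigma_p**2]
    )
    return ContinuousModel(A=A, B=B, Sigma_xi=Sigma_xi, params=params)


def _vanloan_input(A: np.ndarray, B: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """A_dt and B_dt = (int_0^dt e^{As} ds) B via one augmented exponential.

    Valid for singular A (the closed form A^{-1}(A_dt - I)B is recovered when
    A is invertible).
    """
    n, m = B.shape
    M = np.zeros((n + m, n + m))
    M[:n, :n] = A
    M[:n, n:] = B
    E = expm(M * dt)
    return E[:n, :n], E[:n, n:]


def _vanloan_noise(A: np.ndarray, Sigma: np.ndarray, dt: float) -> np.ndarray:
    """Sampled noise covariance int_0^dt e^{As} Sigma e^{A's} ds (Van Loan)."""
    n = A.shape[0]
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = -A
    M[:n, n:] = Sigma
    M[n:, n:] = A.T
    F = expm(M * dt)
    Sigma_dt = F[n:, n:].T @ F[:n, n:]
    return 0.5 * (Sigma_dt + Sigma_dt.T)


def discretize_dynamics(model: ContinuousModel, dt: float = DEFAULT_DT) -> DiscreteModel:
    """Exact zero-order-hold discretization of dynamics and process noise.

    A_dt = exp(A dt); B_dt integrates the input response over one step; the
    sampled covariance Sigma_dt solves the Lyapunov relation
    A Sigma_dt + Sigma_dt A' = A_dt Sigma_xi A_dt' - Sigma_xi and equals the
    integral of e^{As} Sigma_xi e^{A's} over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    A_dt, B_dt = _vanloan_input(model.A, model.B, dt)
    Sigma_dt = _vanloan_noise(model.A, model.Sigma_xi, dt)
    return DiscreteModel(A_dt=A_dt, B_dt=B_dt, Sigma_dt=Sigma_dt, dt=dt)


def discretize_cost(
    model: ContinuousModel, cost: CostMatrices, dt: float = DEFAULT_DT
) -> CostMatrices:
    """Zero-order-hold discretization of the quadratic cost weights.

    Builds the block matrix [[-C', W], [0, C]] dt with C = [[A, B], [0, 0]]
    and W = [[Q, N], [N', R]]; its exponential [[Phi11, Phi12], [0, Phi22]]
    yields the sampled weights Phi22' Phi12, i.e. the exact integral of the
    continuous quadratic form along one held step.  First-order behavior:
    Q_dt ~ Q dt, R_dt ~ R dt, N_dt ~ N dt as dt -> 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n, m = model.B.shape
    C = np.zeros((n + m, n + m))
    C[:n, :n] = model.A
    C[:n, n:] = model.B
    W = cost.stacked()
    Z = np.zeros((2 * (n + m), 2 * (n + m)))
    Z[: n + m, : n + m] = -C.T
    Z[: n + m, n + m :] = W
    Z[n + m :, n + m :] = C
    G = expm(Z * dt)
    W_dt = G[n + m :, n + m :].T @ G[: n + m, n + m :]
    W_dt = 0.5 * (W_dt + W_dt.T)
    # clip tiny negative eigenvalue noise so the container invariants hold
    return CostMatrices(
        Q=W_dt[:n, :n], R=W_dt[n:, n:], N=W_dt[:n, n:]
    )
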