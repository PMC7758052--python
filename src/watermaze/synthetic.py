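"""Synthetic cohorts with the statistical structure of the emulated study.

The design: 51 mice (wildtype: 11 males, 13 females; heterozygous mutants:
12 males, 15 females), trained over 4 days with 4 trials per day, one from
each release location (E, S, NE, SW) in randomized order, 60 s trial cap,
5 Hz tracking.  Learning is encoded entirely in a per-mouse, per-day
trade-off weight beta drawn around day means that rise steeply across
training; group differences beyond the beta schedule are modelled only
through flotation — injected zero-control episodes, consistent with floating
being naive (uncontrolled) behavior.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .control import FeedbackGain, ParamGain, beta_policy, cost_from_gain, expand_param_gain
from .model import (
    DiscreteModel,
    FreeModelParams,
    TankGeometry,
    Trajectory,
    build_continuous_model,
    discretize_cost,
    discretize_dynamics,
)
from .simulate import simulate_trajectory

__all__ = ["CohortConfig", "generate_cohort", "exclusion_filter", "corrupt_trials"]

#: Fitted structured-gain parameters used as the generative controller.
DEFAULT_GAIN = ParamGain(K_r=0.20, K_t=0.38, K_alpha=0.89)

MANIFEST_COLUMNS = [
    "mouse_id", "genotype", "sex", "day", "trial_idx", "release",
    "beta", "n_samples",
]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design constants and generator knobs."""

    group_sizes: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("WT", "M"): 11, ("WT", "F"): 13, ("HET", "M"): 12, ("HET", "F"): 15,
        }
    )
    days: int = 4
    releases: Sequence[str] = ("E", "S", "NE", "SW")
    dt: float = 0.2
    cap_s: float = 60.0
    beta_day_means: Sequence[float] = (0.22, 4.5, 36.8, 475.0)
    #: lognormal jitter of per-mouse-day beta, sd on the log10 scale
    beta_mouse_jitter: float = 0.5
    #: (genotype, sex) -> per-trial probability of an injected flotation episode
    float_injection: Mapping[tuple[str, str], float] = field(default_factory=dict)
    #: injected episode duration range (s), drawn uniformly
    float_duration_s: tuple[float, float] = (1.0, 3.0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if any(b <= 0 for b in self.beta_day_means):
            raise ValueError("beta day means must be positive")
        if len(self.beta_day_means) != self.days:
            raise ValueError("need one beta day mean per training day")

    @property
    def n_mice(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def n_trials(self) -> int:
        return self.n_mice * self.days * len(self.releases)

    @property
    def max_steps(self) -> int:
        return int(round(self.cap_s / self.dt))


def _mouse_roster(cfg: CohortConfig) -> list[tuple[str, str, str]]:
    roster = []
    for (genotype, sex), n in cfg.group_sizes.items():
        for i in range(n):
            roster.append((f"{genotype}-{sex}-{i + 1:02d}", genotype, sex))
    return roster


def generate_cohort(
    cfg: CohortConfig | None = None,
    params: FreeModelParams | None = None,
    gain: FeedbackGain | None = None,
    geometry: TankGeometry | None = None,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate the full cohort; returns trials and their manifest.

    Per mouse and day a beta is drawn around the day mean (lognormal jitter),
    the corresponding complexity-constrained controller is solved, and one
    trial is simulated per release location in a randomized daily order.
    Each animal's very first trial (day 1, first release) is generated from
    the free model (beta = 0): a mouse that has never seen the maze swims
    naively, which is what the first-trial stage of the estimation protocol
    assumes.  Flotation episodes (zero control for 1-3 s) are injected per
    the group configuration.  Fully deterministic given ``cfg.master_seed``.
    """
    cfg = cfg or CohortConfig()
    params = params or FreeModelParams()
    gain = gain or expand_param_gain(DEFAULT_GAIN)
    geometry = geometry or TankGeometry()
    cmodel = build_continuous_model(params)
    dmodel = discretize_dynamics(cmodel, cfg.dt)
    dcost = discretize_cost(cmodel, cost_from_gain(gain), cfg.dt)

    trials: list[Trajectory] = []
    rows = []
    for mi, (mouse_id, genotype, sex) in enumerate(_mouse_roster(cfg)):
        p_float = cfg.float_injection.get((genotype, sex), 0.0)
        for day in range(1, cfg.days + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.master_seed), mi, day])
            )
            log10_beta = np.log10(cfg.beta_day_means[day - 1]) + (
                cfg.beta_mouse_jitter * rng.standard_normal()
            )
            beta = 10.0 ** np.clip(log10_beta, -8.0, 11.0)
            try:
                policy = beta_policy(dmodel, dcost, float(beta))
            except RuntimeError:
                beta = float(np.clip(beta, 1e-4, 1e6))
                policy = beta_policy(dmodel, dcost, beta)
            order = rng.permutation(len(cfg.releases))
            for trial_idx, oi in enumerate(order, start=1):
                release = cfg.releases[oi]
                naive = day == 1 and trial_idx == 1
                trial_policy = None if naive else policy
                trial_beta = 0.0 if naive else float(beta)
                gate = brake = None
                if p_float > 0 and rng.random() < p_float:
                    dur = rng.uniform(*cfg.float_duration_s)
                    n_dur = max(1, int(round(dur / cfg.dt)))
                    # floats happen mid-swim: onset within the first ~12 s,
                    # which nearly every trial is still running
                    onset = rng.integers(6, min(60, cfg.max_steps - n_dur))
                    gate = np.ones(cfg.max_steps)
                    gate[onset : onset + n_dur] = 0.0
                    # a floating mouse stops thrusting and loses speed far
                    # faster than the swimming-fitted damping implies
                    brake = np.ones(cfg.max_steps)
                    brake[onset : onset + n_dur] = 0.2
                x0 = np.array([*geometry.release_points[release], 0.0, 0.0])
                traj, _ = simulate_trajectory(
                    dmodel, trial_policy, x0, geometry,
                    max_steps=cfg.max_steps,
                    seed=rng,
                    control_gate=gate,
                    velocity_brake=brake,
                    mouse_id=mouse_id, genotype=genotype, sex=sex,
                    day=day, trial_idx=trial_idx, release=release,
                )
                trials.append(traj)
                rows.append(
                    {
                        "mouse_id": mouse_id, "genotype": genotype, "sex": sex,
                        "day": day, "trial_idx": trial_idx, "release": release,
                        "beta": trial_beta, "n_samples": len(traj),
                    }
                )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return trials, manifest


def exclusion_filter(
    trials: Sequence[Trajectory], max_missing_frac: float = 0.05
) -> list[Trajectory]:
    """Drop trials with measurement errors or too many missing samples.

    A row with both coordinates NaN counts as a missing sample (tracker
    dropout) and is tolerated up to ``max_missing_frac`` of the trial; any
    other non-finite value (a half-missing row or an infinity) counts as a
    measurement error and excludes the trial outright.
    """
    kept = []
    for tr in trials:
        finite = np.isfinite(tr.positions)
        row_missing = ~finite.all(axis=1)
        full_row_missing = ~finite.any(axis=1)
        if (row_missing & ~full_row_missing).any():
            continue
        if full_row_missing.mean() > max_missing_frac:
            continue
        kept.append(tr)
    return kept


def corrupt_trials(
    trials: Sequence[Trajectory], n: int, seed: int = 0
) -> list[Trajectory]:
    """Testing injector: return a copy with ``n`` trials corrupted.

    Half of the chosen trials get a block of fully-missing samples exceeding
    the default 5% threshold, half get a single half-missing sample; both
    kinds fail ``exclusion_filter``.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(trials), size=n, replace=False)
    out = [replace(tr) for tr in trials]
    for j, i in enumerate(idx):
        tr = out[i]
        pos = tr.positions.copy()
        if j % 2 == 0:
            n_bad = max(1, int(0.10 * len(pos)))
            start = rng.integers(0, max(1, len(pos) - n_bad))
            pos[start : start + n_bad, :] = np.nan
        else:
            pos[rng.integers(0, len(pos)), 0] = np.nan
        out[i] = replace(tr, positions=pos)
    return out
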