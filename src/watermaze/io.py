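"""Readers, writers and run configuration.

File formats (all plain text):

* trajectory CSV — columns ``time_s,x_cm,y_cm``, header required, time
  strictly increasing, floats written with 9 significant digits;
* cohort manifest CSV — one row per trial with mouse/trial metadata and the
  relative path of its trajectory file;
* metrics CSV — one row per trial with all per-trial metrics plus metadata;
* frontier CSV — one row per (release, beta) frontier point;
* fit-result JSON — fitted parameters, likelihood, diagnostics;
* run configuration YAML/JSON — geometry, time step, model parameters,
  solver tolerances, frontier grid and seeds; round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .control import FeedbackGain, ParamGain
from .estimation import BetaSchedule, FitResult
from .model import FreeModelParams, TankGeometry, Trajectory
from .simulate import FrontierGrid, VCCurve

__all__ = [
    "ParseError",
    "RunConfig",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_manifest",
    "write_cohort",
    "read_cohort",
    "write_metrics_table",
    "write_frontier_csv",
    "write_fit_result",
    "read_fit_result",
]

# 12 significant digits: keeps the read-back error below 1e-9 for
# tank-scale coordinates
FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Structured parse failure: file, line and reason."""

    def __init__(self, path, line: int | None, reason: str):
        self.path = str(path)
        self.line = line
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {reason}")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = traj.times
    with open(path, "w") as fh:
        fh.write("time_s,x_cm,y_cm\n")
        for ti, (x, y) in zip(t, traj.positions):
            fh.write(
                f"{FLOAT_FMT % ti},{FLOAT_FMT % x},{FLOAT_FMT % y}\n"
            )


def read_trajectory_csv(path, **meta) -> Trajectory:
    """Parse one trial; malformed rows are reported with line numbers."""
    path = Path(path)
    if not path.exists():
        raise ParseError(path, None, "file not found")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(path, None, "empty file")
    header = [c.strip() for c in lines[0].split(",")]
    required = ["time_s", "x_cm", "y_cm"]
    if header[:3] != required:
        raise ParseError(path, 1, f"expected header {','.join(required)}, got {lines[0]!r}")
    times, xs, ys = [], [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) < 3:
            raise ParseError(path, ln, f"expected 3 columns, got {len(parts)}")
        try:
            t, x, y = (float(parts[0]), float(parts[1]), float(parts[2]))
        except ValueError:
            raise ParseError(path, ln, f"non-numeric value in {line!r}") from None
        times.append(t)
        xs.append(x)
        ys.append(y)
    if len(times) < 2:
        raise ParseError(path, None, "a trajectory needs at least 2 samples")
    times = np.array(times)
    dts = np.diff(times)
    if (dts <= 0).any():
        bad = int(np.argmax(dts <= 0))
        raise ParseError(path, bad + 3, "time_s must be strictly increasing")
    dt = float(np.median(dts))
    return Trajectory(
        positions=np.column_stack([xs, ys]), dt=dt, **meta
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _trial_filename(row) -> str:
    return f"trials/{row['mouse_id']}_d{row['day']}_t{row['trial_idx']}.csv"


def write_cohort(trials, manifest: pd.DataFrame, outdir) -> Path:
    """Write trial CSVs plus the manifest; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "trials").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for tr, (_, row) in zip(trials, manifest.iterrows()):
        rel = _trial_filename(row)
        write_trajectory_csv(tr, outdir / rel)
        paths.append(rel)
    manifest["path"] = paths
    mpath = outdir / "manifest.csv"
    manifest.to_csv(mpath, index=False, float_format=FLOAT_FMT)
    return mpath


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(path, None, "manifest not found")
    df = pd.read_csv(path)
    required = {"mouse_id", "genotype", "sex", "day", "trial_idx", "release", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"manifest missing columns: {sorted(missing)}")
    return df


def read_cohort(cohort_dir) -> tuple[list[Trajectory], pd.DataFrame]:
    """Load every trial referenced by a cohort directory's manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = read_manifest(cohort_dir / "manifest.csv")
    trials = []
    for _, row in manifest.iterrows():
        tpath = cohort_dir / row["path"]
        if not tpath.exists():
            raise ParseError(tpath, None, f"trial file referenced by manifest is missing")
        trials.append(
            read_trajectory_csv(
                tpath,
                mouse_id=row["mouse_id"], genotype=row["genotype"],
                sex=row["sex"], day=int(row["day"]),
                trial_idx=int(row["trial_idx"]), release=row["release"],
            )
        )
    return trials, manifest


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_metrics_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_frontier_csv(curves: dict[str, VCCurve], path) -> None:
    rows = []
    for release, c in curves.items():
        for b, v, i in zip(c.betas, c.mean_value, c.mean_complexity):
            rows.append(
                {
                    "release": release, "beta": b,
                    "mean_value": v, "mean_complexity": i,
                    "n_reps": c.n_reps, "seed": c.seed,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_fit_result(result, path, kind: str, seed: int | None = None) -> None:
    """Serialize a FitResult or {mouse: BetaSchedule} mapping to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc: dict = {"kind": kind, "seed": seed}
    if isinstance(result, FitResult):
        p = result.params
        if isinstance(p, FreeModelParams):
            doc["params"] = dataclasses.asdict(p)
        elif isinstance(p, FeedbackGain):
            doc["params"] = {"K": p.K.tolist()}
        elif isinstance(p, ParamGain):
            doc["params"] = dataclasses.asdict(p)
        else:
            doc["params"] = _jsonify(p)
        doc.update(
            loglik=result.loglik, n_obs=result.n_obs,
            converged=result.converged,
            diagnostics=_jsonify(result.diagnostics),
        )
    elif isinstance(result, dict):  # beta schedules
        doc["schedules"] = {
            mid: {
                "b0": s.b0, "b1": s.b1, "b2": s.b2,
                "beta_by_day": {str(d): v for d, v in s.beta_by_day.items()},
                "per_day_profile": {str(d): v for d, v in s.per_day_profile.items()},
                "loglik": s.loglik, "converged": s.converged,
            }
            for mid, s in result.items()
        }
    else:
        raise TypeError(f"cannot serialize {type(result)!r}")
    with open(path, "w") as fh:
        json.dump(_jsonify(doc), fh, indent=2)


def read_fit_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_free_params(doc: dict) -> FreeModelParams:
    return FreeModelParams(**doc["params"])


def load_gain(doc: dict) -> FeedbackGain:
    p = doc["params"]
    if "K" in p:
        return FeedbackGain(K=np.asarray(p["K"], dtype=float))
    from .control import expand_param_gain

    return expand_param_gain(ParamGain(**p))


def load_beta_schedules(doc: dict) -> dict[str, BetaSchedule]:
    out = {}
    for mid, s in doc["schedules"].items():
        out[mid] = BetaSchedule(
            mouse_id=mid, b0=s["b0"], b1=s["b1"], b2=s["b2"],
            beta_by_day={int(d): v for d, v in s["beta_by_day"].items()},
            per_day_profile={int(d): v for d, v in s.get("per_day_profile", {}).items()},
            loglik=s.get("loglik", math.nan), converged=s.get("converged", True),
        )
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a run; round-trips through YAML/JSON."""

    dt: float = 0.2
    params: FreeModelParams = dataclasses.field(default_factory=FreeModelParams)
    gain: ParamGain = dataclasses.field(
        default_factory=lambda: ParamGain(K_r=0.20, K_t=0.38, K_alpha=0.89)
    )
    tank_radius: float = 60.0
    platform_radius: float = 5.0
    platform_polar: tuple[float, float] = (30.0, 135.0)  # (radius cm, angle deg)
    release_radius: float = 55.0
    riccati_tol: float = 1e-8
    grid: FrontierGrid = dataclasses.field(default_factory=FrontierGrid)
    seed: int = 0
    paths: dict = dataclasses.field(default_factory=dict)

    def geometry(self) -> TankGeometry:
        r, a = self.platform_polar
        center = np.array(
            [r * math.cos(math.radians(a)), r * math.sin(math.radians(a))]
        )
        pts = {
            lab: self.release_radius
            * np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
            for lab, ang in [("E", 0.0), ("S", -90.0), ("NE", 45.0), ("SW", -135.0)]
        }
        return TankGeometry(
            radius=self.tank_radius,
            platform_center=center,
            platform_radius=self.platform_radius,
            release_points=pts,
        )

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "params": dataclasses.asdict(self.params),
            "gain": dataclasses.asdict(self.gain),
            "tank_radius": self.tank_radius,
            "platform_radius": self.platform_radius,
            "platform_polar": list(self.platform_polar),
            "release_radius": self.release_radius,
            "riccati_tol": self.riccati_tol,
            "grid": dataclasses.asdict(self.grid),
            "seed": self.seed,
            "paths": dict(self.paths),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            dt=d.get("dt", 0.2),
            params=FreeModelParams(**d.get("params", {})),
            gain=ParamGain(**d.get("gain", dataclasses.asdict(cls().gain))),
            tank_radius=d.get("tank_radius", 60.0),
            platform_radius=d.get("platform_radius", 5.0),
            platform_polar=tuple(d.get("platform_polar", (30.0, 135.0))),
            release_radius=d.get("release_radius", 55.0),
            riccati_tol=d.get("riccati_tol", 1e-8),
            grid=FrontierGrid(**d.get("grid", {})),
            seed=d.get("seed", 0),
            paths=dict(d.get("paths", {})),
        )

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d)
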