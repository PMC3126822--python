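"""Trajectory containers and delimited-table input/output.

The on-disk format is a plain UTF-8 CSV with a mandatory header row::

    sample_id,condition,particle_id,frame,t_s,x_um,y_um

Coordinates are micrometres, time is seconds, frame indices are 0-based.
The time column is authoritative; the frame column is advisory. Lines
starting with ``#`` are comments (the CLI writes provenance there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ["sample_id", "condition", "particle_id", "frame", "t_s", "x_um", "y_um"]
SUMMARY_COLUMNS = ["sample_id", "condition", "particle_id", "deff_1s_um2_s", "alpha", "immobile"]

#: maximum relative jitter tolerated in frame spacing
_MAX_REL_JITTER = 1e-6


class TrajectoryError(ValueError):
    """Raised for malformed trajectory tables or invalid trajectories."""


@dataclass(frozen=True)
class Trajectory:
    """One particle's time-ordered 2-D centroid positions at uniform spacing."""

    sample_id: str
    condition: str
    particle_id: str
    times: np.ndarray  # s
    x: np.ndarray  # µm
    y: np.ndarray  # µm

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if times.ndim != 1 or times.size < 2:
            raise TrajectoryError(
                f"particle {self.particle_id!r}: needs >= 2 time points, got {times.size}"
            )
        if x.shape != times.shape or y.shape != times.shape:
            raise TrajectoryError(f"particle {self.particle_id!r}: x/y/time length mismatch")
        if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(times).all()):
            raise TrajectoryError(f"particle {self.particle_id!r}: non-finite coordinate or time")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise TrajectoryError(f"particle {self.particle_id!r}: times not strictly increasing")
        mean_dt = dt.mean()
        if (dt.max() - dt.min()) > _MAX_REL_JITTER * mean_dt:
            raise TrajectoryError(
                f"particle {self.particle_id!r}: non-uniform time steps "
                f"(spread {dt.max() - dt.min():.3g} s around {mean_dt:.6g} s); "
                "check for dropped frames"
            )

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def frame_interval(self) -> float:
        return float(np.diff(self.times).mean())

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class TrackingExperiment:
    """A set of trajectories sharing one frame interval, grouped by (sample, condition)."""

    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trajectories:
            dts = np.array([t.frame_interval for t in self.trajectories])
            ref = dts[0]
            if np.any(np.abs(dts - ref) > 1e-6 * ref):
                raise TrajectoryError("trajectories do not share a common frame interval")

    @property
    def frame_interval(self) -> float:
        if not self.trajectories:
            raise TrajectoryError("empty experiment has no frame interval")
        return self.trajectories[0].frame_interval

    @property
    def duration(self) -> float:
        return max(t.duration for t in self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def groups(self) -> dict[tuple[str, str], list[Trajectory]]:
        """Trajectories keyed by (sample_id, condition), insertion-ordered."""
        out: dict[tuple[str, str], list[Trajectory]] = {}
        for t in self.trajectories:
            out.setdefault((t.sample_id, t.condition), []).append(t)
        return out

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trajectories:
            seen.setdefault(t.condition)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trajectories:
            dt = t.frame_interval
            frames = np.rint((t.times - t.times[0]) / dt).astype(int)
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": t.sample_id,
                        "condition": t.condition,
                        "particle_id": t.particle_id,
                        "frame": frames,
                        "t_s": t.times,
                        "x_um": t.x,
                        "y_um": t.y,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
        df = pd.concat(rows, ignore_index=True)
        return df.sort_values(
            ["sample_id", "condition", "particle_id", "t_s"], kind="stable"
        ).reset_index(drop=True)


def experiment_from_frame(df: pd.DataFrame) -> TrackingExperiment:
    """Build a validated experiment from a trajectory-table DataFrame."""
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"trajectory table is missing columns {missing}")
    df = df.sort_values(["sample_id", "condition", "particle_id", "t_s"], kind="stable")
    dup = df.duplicated(subset=["sample_id", "condition", "particle_id", "t_s"])
    if dup.any():
        row = int(df.index[dup][0])
        raise TrajectoryError(f"duplicate (particle, time) entry at input row {row}")
    trajectories = []
    for (sample_id, condition, particle_id), grp in df.groupby(
        ["sample_id", "condition", "particle_id"], sort=False
    ):
        trajectories.append(
            Trajectory(
                sample_id=str(sample_id),
                condition=str(condition),
                particle_id=str(particle_id),
                times=grp["t_s"].to_numpy(float),
                x=grp["x_um"].to_numpy(float),
                y=grp["y_um"].to_numpy(float),
            )
        )
    return TrackingExperiment(trajectories)


def read_trajectories(path: str | Path) -> TrackingExperiment:
    """Read and validate a trajectory table.

    Raises :class:`TrajectoryError` on malformed headers, duplicate
    (particle, time) rows, or non-uniform time steps (dropped frames),
    naming the offending particle or row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype={"sample_id": str, "condition": str, "particle_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrajectoryError(f"{path}: cannot parse trajectory table: {exc}") from exc
    header = list(df.columns)
    if header != TRAJECTORY_COLUMNS:
        raise TrajectoryError(
            f"{path}: malformed header {header}; expected {TRAJECTORY_COLUMNS}"
        )
    for col in ("t_s", "x_um", "y_um"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2  # 1-based incl. header
            raise TrajectoryError(f"{path}: missing {col} value at line {row}")
    return experiment_from_frame(df)


def write_trajectories(
    experiment: TrackingExperiment, path: str | Path, header_comment: str | None = None
) -> None:
    """Write an experiment as a deterministic, sorted CSV (full float precision)."""
    path = Path(path)
    df = experiment.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    """Read a per-particle summary table (deff_1s_um2_s, alpha, immobile)."""
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str, "condition": str, "particle_id": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"{path}: summary table is missing columns {missing}")
    return df


def write_summary(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, columns=[c for c in SUMMARY_COLUMNS if c in df.columns])
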