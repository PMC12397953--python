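"""Basic behavioral metrics at native 5 Hz and per-interval CoV plasticity.

Three per-frame metrics retain the full 0.2 s resolution of the tracking:

* **step length** — Euclidean distance between consecutive positions (cm),
  an instantaneous activity measure;
* **turning angle** — signed angle between consecutive movement vectors
  (radians, counterclockwise positive, wrapped to (-pi, pi]);
* **wall distance** — distance to the nearest tank wall segment (cm), a
  relative spatial-position measure.

Plasticity in each single metric is the coefficient of variation (sd/mean)
within hour- or day-length intervals of developmental time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tracks import NOMINAL_DT, TankPolygon, Trajectory

__all__ = [
    "IntervalSpec",
    "MetricSeries",
    "step_lengths",
    "turning_angles",
    "wall_distances",
    "compute_metrics",
    "metrics_frame",
    "coefficient_of_variation",
    "METRICS",
]

METRICS = ("step", "turn", "wall")


@dataclass(frozen=True)
class IntervalSpec:
    """Binning of developmental time into observation intervals.

    ``kind`` is ``"hour"`` or ``"day"``.  ``seconds_per_hour`` is 3600 for
    real recordings; the scaled-down synthetic presets shrink it so a
    cohort keeps its 8 x 28 interval structure at a fraction of the frames.
    Interval indices are 1-based and aligned to observation-day starts.
    """

    kind: str = "hour"
    seconds_per_hour: float = 3600.0
    hours_per_day: int = 8

    def __post_init__(self):
        if self.kind not in ("hour", "day"):
            raise ValueError("interval kind must be 'hour' or 'day'")

    @property
    def nominal_frames(self) -> int:
        """Frames in one complete interval at the nominal 5 Hz."""
        per_hour = int(round(self.seconds_per_hour / NOMINAL_DT))
        return per_hour if self.kind == "hour" else per_hour * self.hours_per_day

    def index_for(self, day_index, time_s) -> np.ndarray:
        """Map (observation day, seconds within day) to a 1-based interval index."""
        day = np.asarray(day_index, dtype=int)
        if self.kind == "day":
            return day
        hour_in_day = np.minimum(
            (np.asarray(time_s, float) / self.seconds_per_hour).astype(int),
            self.hours_per_day - 1,
        )
        return (day - 1) * self.hours_per_day + hour_in_day + 1

    def hour_of_interval(self, interval_index) -> np.ndarray:
        """Observation-hour coordinate (midpoint-free, 1-based) of an interval.

        For hourly binning this is the interval index itself; for daily
        binning it is the middle observation hour of the day, so that arc
        fits on the two scales share a time axis.
        """
        idx = np.asarray(interval_index, dtype=float)
        if self.kind == "hour":
            return idx
        return (idx - 1) * self.hours_per_day + (self.hours_per_day + 1) / 2.0


@dataclass
class MetricSeries:
    """Per-frame metric values for one individual-day, with validity masks."""

    individual_id: str
    day_index: int
    time_s: np.ndarray
    step_cm: np.ndarray
    turn_rad: np.ndarray
    wall_cm: np.ndarray
    step_valid: np.ndarray
    turn_valid: np.ndarray
    wall_valid: np.ndarray
    mother_id: str = "NA"
    tank_position: str = "NA"
    tank_system: str = "NA"

    def __len__(self) -> int:
        return len(self.time_s)

    def values(self, metric: str) -> tuple[np.ndarray, np.ndarray]:
        return getattr(self, f"{metric}_cm" if metric != "turn" else "turn_rad"), getattr(
            self, f"{metric}_valid"
        )


def step_lengths(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean displacement per frame; undefined at the first frame.

    ``step[t] = ||p[t] - p[t-1]||`` and is valid only where both frames are
    valid and exactly one nominal sampling interval apart, so un-filled
    dropouts never produce spurious large steps.
    """
    n = len(traj)
    step = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if n < 2:
        return step, valid
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    adjacent = np.abs(np.diff(traj.time_s) - NOMINAL_DT) < 1e-4
    ok = traj.valid[1:] & traj.valid[:-1] & adjacent
    step[1:][ok] = np.hypot(dx[ok], dy[ok])
    valid[1:] = ok
    return step, valid


def turning_angles(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Signed turn between consecutive movement vectors, CCW positive.

    The angle at frame ``t`` rotates the vector ``p[t-1]-p[t-2]`` onto
    ``p[t]-p[t-1]`` and is wrapped to (-pi, pi] with an exact reversal
    mapping to +pi.  It is undefined whenever either movement vector has
    zero length (bearing of a motionless animal is meaningless) or the
    three frames are not consecutive valid samples.
    """
    n = len(traj)
    turn = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if n < 3:
        return turn, valid
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    adjacent = np.abs(np.diff(traj.time_s) - NOMINAL_DT) < 1e-4
    seg_ok = traj.valid[1:] & traj.valid[:-1] & adjacent
    v1x, v1y = dx[:-1], dy[:-1]
    v2x, v2y = dx[1:], dy[1:]
    moving = (np.hypot(v1x, v1y) > 0) & (np.hypot(v2x, v2y) > 0)
    ok = seg_ok[:-1] & seg_ok[1:] & moving
    cross = v1x * v2y - v1y * v2x
    dot = v1x * v2x + v1y * v2y
    with np.errstate(invalid="ignore"):
        ang = np.arctan2(cross, dot)  # (-pi, pi], reversal -> +pi
    turn[2:][ok] = ang[ok]
    valid[2:] = ok
    return turn, valid


def wall_distances(traj: Trajectory, tank: TankPolygon) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each valid position to the nearest wall segment (cm)."""
    n = len(traj)
    wall = np.full(n, np.nan)
    valid = traj.valid.copy()
    if valid.any():
        wall[valid] = tank.boundary_distance(traj.x[valid], traj.y[valid])
    return wall, valid


def compute_metrics(traj: Trajectory, tank: TankPolygon) -> MetricSeries:
    step, sv = step_lengths(traj)
    turn, tv = turning_angles(traj)
    wall, wv = wall_distances(traj, tank)
    return MetricSeries(
        individual_id=traj.individual_id,
        day_index=traj.day_index,
        time_s=traj.time_s,
        step_cm=step,
        turn_rad=turn,
        wall_cm=wall,
        step_valid=sv,
        turn_valid=tv,
        wall_valid=wv,
        mother_id=traj.mother_id,
        tank_position=traj.tank_position,
        tank_system=traj.tank_system,
    )


def metrics_frame(series_list: list[MetricSeries]) -> pd.DataFrame:
    """Stack per-day metric series into one long frame (NaN where invalid)."""
    frames = []
    for ms in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ms.individual_id,
                    "mother_id": ms.mother_id,
                    "tank_position": ms.tank_position,
                    "tank_system": ms.tank_system,
                    "day_index": ms.day_index,
                    "time_s": ms.time_s,
                    "step": np.where(ms.step_valid, ms.step_cm, np.nan),
                    "turn": np.where(ms.turn_valid, ms.turn_rad, np.nan),
                    "wall": np.where(ms.wall_valid, ms.wall_cm, np.nan),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def coefficient_of_variation(
    metrics: pd.DataFrame,
    interval: IntervalSpec,
    *,
    abs_turn: bool = True,
    ddof: int = 1,
    min_frames_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-individual, per-interval CoV (sd / mean) for each metric.

    Signed turning angles average to ~0, which makes sd/mean ill-posed, so
    the turning-angle CoV is computed on ``|turn|`` by default (variability
    of turn magnitude); set ``abs_turn=False`` to use the signed values.
    ``ddof=1`` selects the sample standard deviation.  Intervals with fewer
    than ``min_frames_frac`` of the nominal frame count, or with
    non-positive mean, yield NaN rather than a number.

    Returns a long frame with columns individual_id, mother_id,
    tank_position, tank_system, interval_index, metric, cov, n_frames.
    """
    df = metrics.copy()
    df["interval_index"] = interval.index_for(df["day_index"], df["time_s"])
    if abs_turn:
        df["turn"] = df["turn"].abs()
    min_frames = max(2, int(np.ceil(min_frames_frac * interval.nominal_frames)))
    keys = ["individual_id", "mother_id", "tank_position", "tank_system", "interval_index"]
    long = df.melt(
        id_vars=keys, value_vars=list(METRICS), var_name="metric", value_name="value"
    ).dropna(subset=["value"])
    g = long.groupby(keys + ["metric"], sort=True, observed=True)["value"]
    out = g.agg(n_frames="count", mean="mean", sd=lambda v: v.std(ddof=ddof)).reset_index()
    ok = (out["n_frames"] >= min_frames) & (out["mean"] > 0)
    out["cov"] = np.where(ok, out["sd"] / out["mean"], np.nan)
    return out[keys + ["metric", "cov", "n_frames"]]
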