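"""Reading, validating and gap-filling raw 2-D track tables, plus tank geometry.

The on-disk model is a long CSV of timestamped x-y positions (one row per
video frame at a nominal 5 Hz), with one track per individual per
observation day.  All coordinates are in centimetres and all times in
seconds; unit conversion happens at ingest or not at all.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Polygon

__all__ = [
    "TrackDialect",
    "DEFAULT_DIALECT",
    "TankPolygon",
    "equilateral_tank",
    "Trajectory",
    "TrackFormatError",
    "TrackDataError",
    "QCReport",
    "read_tracks",
    "write_tracks",
    "fill_gaps",
    "check_inside",
]

NOMINAL_DT = 0.2  # s, 5 Hz tracking
_DT_TOL = 1e-6


class TrackFormatError(ValueError):
    """The file does not match the expected tabular layout."""


class TrackDataError(ValueError):
    """The file parses but its contents violate a data invariant."""


@dataclass(frozen=True)
class TrackDialect:
    """Column-name mapping from an on-disk CSV to the canonical track fields.

    Only ``id``, ``day``, ``time``, ``x`` and ``y`` are required in the
    file; the cohort covariates default to placeholder values when their
    columns are absent.
    """

    id: str = "id"
    day: str = "day"
    time: str = "time"
    x: str = "x"
    y: str = "y"
    mother: str = "mother"
    position: str = "position"
    system: str = "system"

    @property
    def required(self) -> dict[str, str]:
        return {k: getattr(self, k) for k in ("id", "day", "time", "x", "y")}

    @property
    def covariates(self) -> dict[str, str]:
        return {k: getattr(self, k) for k in ("mother", "position", "system")}


DEFAULT_DIALECT = TrackDialect()


class TankPolygon:
    """A convex, counterclockwise tank outline in cm.

    Wraps a :class:`shapely.geometry.Polygon` and exposes the geometric
    queries the pipeline needs (containment, boundary distance, boundary
    projection).
    """

    def __init__(self, vertices):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("tank polygon needs >= 3 (x, y) vertices")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("tank polygon must be simple with positive area")
        hull = poly.convex_hull
        if abs(hull.area - poly.area) > 1e-9 * hull.area:
            raise ValueError("tank polygon must be convex")
        if poly.exterior.is_ccw:
            self.vertices = v
        else:  # normalize orientation
            self.vertices = v[::-1].copy()
        self._poly = Polygon(self.vertices)

    @property
    def polygon(self) -> Polygon:
        return self._poly

    @property
    def area(self) -> float:
        return self._poly.area

    @property
    def centroid(self) -> np.ndarray:
        c = self._poly.centroid
        return np.array([c.x, c.y])

    @property
    def inradius(self) -> float:
        """Radius of the largest circle that fits inside the tank."""
        return float(shapely.length(shapely.maximum_inscribed_circle(self._poly)))

    def contains(self, x, y) -> np.ndarray:
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(self._poly, pts)

    def boundary_distance(self, x, y) -> np.ndarray:
        """Unsigned distance from (x, y) to the nearest wall segment."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.distance(self._poly.exterior, pts)

    def signed_outside_distance(self, x, y) -> np.ndarray:
        """Distance to the boundary, positive outside the tank, 0 inside."""
        d = self.boundary_distance(x, y)
        return np.where(self.contains(x, y), 0.0, d)

    def project_to_boundary(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        ring = self._poly.exterior
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        s = shapely.line_locate_point(ring, shapely.points(x, y))
        proj = shapely.line_interpolate_point(ring, s)
        return shapely.get_x(proj), shapely.get_y(proj)

    @classmethod
    def from_config(cls, path) -> "TankPolygon":
        """Load a tank outline from a small YAML/JSON config.

        Expected layout: ``{"vertices": [[x1, y1], [x2, y2], ...]}`` in cm.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict) or "vertices" not in cfg:
            raise TrackFormatError(f"{path}: tank config needs a 'vertices' key")
        return cls(cfg["vertices"])

    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"vertices": np.asarray(self.vertices).tolist()}, fh)


def equilateral_tank(side: float = 60.0) -> TankPolygon:
    """Default synthetic arena: an equilateral triangle of the given side (cm).

    The planform of the real rearing tanks is triangular; absent published
    dimensions we use a 60 cm side as a plausible stand-in.
    """
    h = side * np.sqrt(3) / 2
    return TankPolygon([(0.0, 0.0), (side, 0.0), (side / 2, h)])


@dataclass
class Trajectory:
    """One individual's track for one observation day at nominal 5 Hz.

    ``time_s`` is seconds since the start of that day's observation window
    and must be strictly increasing on the nominal 0.2 s grid after
    gap-filling.  ``valid`` marks frames with usable coordinates; x/y are
    NaN wherever ``valid`` is False.
    """

    individual_id: str
    day_index: int
    time_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    mother_id: str = "NA"
    tank_position: str = "NA"
    tank_system: str = "NA"

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time_s)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("trajectory arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            i = int(np.argmin(np.diff(self.time_s)))
            raise TrackDataError(
                f"{self.individual_id} day {self.day_index}: time not strictly "
                f"increasing at row {i + 1} (t={self.time_s[i + 1]!r})"
            )
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if bad.any():
            raise TrackDataError("non-finite coordinates marked valid")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def copy(self) -> "Trajectory":
        return dataclasses.replace(
            self,
            time_s=self.time_s.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            valid=self.valid.copy(),
        )


def read_tracks(path, dialect: TrackDialect = DEFAULT_DIALECT) -> list[Trajectory]:
    """Read a track CSV into one :class:`Trajectory` per (individual, day).

    Rows may arrive in any order; they are sorted by (individual, day,
    time).  Frames with missing coordinates are kept and marked invalid.
    Duplicate timestamps within an individual-day raise
    :class:`TrackDataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in dialect.required.values() if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing required column(s) {missing}")
    d = dialect
    df = df.sort_values([d.id, d.day, d.time], kind="mergesort").reset_index(drop=True)
    out: list[Trajectory] = []
    for (ind, day), g in df.groupby([d.id, d.day], sort=True):
        t = g[d.time].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            i = int(np.argmax(np.diff(t) <= 0))
            row = g.index[i + 1]
            raise TrackDataError(
                f"{path}: non-monotone/duplicate time for individual {ind!r} "
                f"day {day!r} at input row {row} (t={t[i + 1]!r})"
            )
        x = g[d.x].to_numpy(float)
        y = g[d.y].to_numpy(float)
        valid = np.isfinite(x) & np.isfinite(y)
        x = np.where(valid, x, np.nan)
        y = np.where(valid, y, np.nan)

        def _cov(col, default="NA"):
            if col in g.columns:
                return str(g[col].iloc[0])
            return default

        out.append(
            Trajectory(
                individual_id=str(ind),
                day_index=int(day),
                time_s=t,
                x=x,
                y=y,
                valid=valid,
                mother_id=_cov(d.mother),
                tank_position=_cov(d.position),
                tank_system=_cov(d.system),
            )
        )
    return out


def write_tracks(trajs: list[Trajectory], path, dialect: TrackDialect = DEFAULT_DIALECT) -> None:
    """Write trajectories back to the CSV dialect read by :func:`read_tracks`."""
    d = dialect
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    d.id: tr.individual_id,
                    d.day: tr.day_index,
                    d.time: tr.time_s,
                    d.x: tr.x,
                    d.y: tr.y,
                    d.mother: tr.mother_id,
                    d.position: tr.tank_position,
                    d.system: tr.tank_system,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def _invalid_runs(valid: np.ndarray):
    """Yield (start, stop) slices of consecutive invalid frames."""
    idx = np.flatnonzero(~valid)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks] + 1, idx[-1] + 1]
    yield from zip(starts, stops)


def fill_gaps(traj: Trajectory, max_gap_frames: int = 5) -> Trajectory:
    """Regularize a track to the nominal 0.2 s grid and bridge short dropouts.

    Missing rows are first materialized as invalid frames on the nominal
    grid spanning [first, last] observed time.  Runs of at most
    ``max_gap_frames`` invalid frames flanked by valid frames are replaced
    by linear interpolation and marked valid; longer runs are left invalid
    so that downstream metrics split rather than invent movement.  Nothing
    is extrapolated beyond the first/last valid frame.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    if traj.n_valid == 0:
        raise TrackDataError(
            f"{traj.individual_id} day {traj.day_index}: no valid frames"
        )
    t0 = traj.time_s[0]
    n = int(round((traj.time_s[-1] - t0) / NOMINAL_DT)) + 1
    grid = t0 + NOMINAL_DT * np.arange(n)
    pos = np.round((traj.time_s - t0) / NOMINAL_DT).astype(int)
    if np.any(np.abs(traj.time_s - (t0 + pos * NOMINAL_DT)) > 1e-4):
        raise TrackDataError(
            f"{traj.individual_id} day {traj.day_index}: timestamps not on the "
            f"nominal {NOMINAL_DT} s grid"
        )
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    x[pos] = traj.x
    y[pos] = traj.y
    valid[pos] = traj.valid

    for start, stop in list(_invalid_runs(valid)):
        if start == 0 or stop == n:
            continue  # no extrapolation
        gap = stop - start
        if gap > max_gap_frames:
            continue
        if not (valid[start - 1] and valid[stop]):
            continue
        w = np.arange(1, gap + 1) / (gap + 1)
        x[start:stop] = x[start - 1] + w * (x[stop] - x[start - 1])
        y[start:stop] = y[start - 1] + w * (y[stop] - y[start - 1])
        valid[start:stop] = True

    return dataclasses.replace(traj, time_s=grid, x=x, y=y, valid=valid)


@dataclass
class QCReport:
    """Containment QC for one trajectory against the tank outline."""

    individual_id: str
    day_index: int
    n_frames: int
    n_outside: int = 0        # > tol outside, flagged invalid
    n_projected: int = 0      # <= tol outside, snapped to the wall
    tol_cm: float = 0.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def check_inside(traj: Trajectory, tank: TankPolygon, tol_cm: float = 0.5) -> tuple[Trajectory, QCReport]:
    """Flag frames outside the tank and snap near-boundary excursions.

    Frames more than ``tol_cm`` outside the polygon are marked invalid;
    frames within the tolerance band (tracking jitter at the wall) are
    projected onto the nearest boundary point.  Frames inside the polygon
    are never moved.
    """
    out = traj.copy()
    rep = QCReport(traj.individual_id, traj.day_index, len(traj), tol_cm=tol_cm)
    v = out.valid
    if not v.any():
        return out, rep
    d_out = tank.signed_outside_distance(out.x[v], out.y[v])
    far = d_out > tol_cm
    near = (d_out > 0) & ~far
    idx = np.flatnonzero(v)
    if far.any():
        bad = idx[far]
        out.valid[bad] = False
        out.x[bad] = np.nan
        out.y[bad] = np.nan
        rep.n_outside = int(far.sum())
    if near.any():
        snap = idx[near]
        px, py = tank.project_to_boundary(out.x[snap], out.y[snap])
        out.x[snap] = px
        out.y[snap] = py
        rep.n_projected = int(near.sum())
    return out, rep
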