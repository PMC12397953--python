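import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bplast as bp
from bplast.io_tracks import Trajectory, equilateral_tank

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tank():
    return equilateral_tank(60.0)


def make_traj(points, t0=0.0, dt=0.2, individual="F01", day=1, valid=None):
    """Build a small Trajectory from a list of (x, y) points."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if valid is None:
        valid = np.isfinite(pts).all(axis=1)
    return Trajectory(
        individual_id=individual,
        day_index=day,
        time_s=t0 + dt * np.arange(n),
        x=np.where(valid, pts[:, 0], np.nan),
        y=np.where(valid, pts[:, 1], np.nan),
        valid=np.asarray(valid, bool),
    )


@pytest.fixture(scope="session")
def mini_cohort():
    """A small simulated cohort: 6 individuals, 6 days, 30 s hour-bins."""
    cfg = bp.desk_preset(n_individuals=6, days=6, seconds_per_hour=30.0, master_seed=7)
    trajs, truth = bp.make_cohort(cfg)
    return cfg, trajs, truth


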