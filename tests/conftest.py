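"""Shared fixtures: tiny landscapes and reusable simulated troops.

Session-scoped simulations keep the suite fast: several test modules share
one home-range ("foraging") run and one day-commute run instead of
re-simulating per test.
"""

import numpy as np
import pandas as pd
import pytest

from troopstep import gen_landscape, simulate_troop, TrajectorySet
from troopstep.landscape import Landscape
from troopstep.synthetic import AgentConfig, LandscapeConfig, FORAGING_BETA


def make_landscape(
    n=40,
    res=1.0,
    veg=None,
    roads=None,
    paths=None,
    elev=None,
    sleep=(20.0, 20.0),
):
    """Small hand-specified landscape for feature unit tests."""
    zeros = np.zeros((n, n))
    return Landscape(
        origin=(0.0, 0.0),
        resolution=res,
        vegetation=zeros.copy() if veg is None else np.asarray(veg, dtype=float),
        roads=zeros.copy() if roads is None else np.asarray(roads, dtype=float),
        paths=zeros.copy() if paths is None else np.asarray(paths, dtype=float),
        elevation=zeros.copy() if elev is None else np.asarray(elev, dtype=float),
        sleep_site=sleep,
    )


def make_trajectories(tracks: dict, t0="2012-08-01 06:00:00") -> TrajectorySet:
    """Build a TrajectorySet from {id: (n, 2) array-with-NaN} at 1 Hz."""
    ids = sorted(tracks)
    n_t = max(len(v) for v in tracks.values())
    xy = np.full((len(ids), n_t, 2), np.nan)
    for i, k in enumerate(ids):
        arr = np.asarray(tracks[k], dtype=float)
        xy[i, : len(arr)] = arr
    times = pd.date_range(t0, periods=n_t, freq="1s")
    return TrajectorySet(ids, times, xy)


@pytest.fixture(scope="session")
def flat_landscape():
    return make_landscape()


@pytest.fixture(scope="session")
def foraging_sim():
    """Cohesive home-range troop: landscape, trajectories, choice log."""
    ls = gen_landscape(
        LandscapeConfig(extent_m=(400.0, 400.0), vegetation_cover_target=0.3, seed=11)
    )
    traj, log = simulate_troop(
        ls,
        AgentConfig(
            n_agents=10,
            n_steps=600,
            beta_true=FORAGING_BETA,
            seed=12,
            start_spread_m=10.0,
            turn_angle_dist=("wrapped_normal", {"sigma": 0.6}),
        ),
    )
    return ls, traj, log


@pytest.fixture(scope="session")
def commute_sim():
    """Full-day commute troop (all time-of-day bins populated)."""
    ls = gen_landscape(LandscapeConfig(extent_m=(1000.0, 1000.0), seed=21))
    traj, log = simulate_troop(
        ls, AgentConfig(n_agents=6, n_steps=2000, seed=22)
    )
    return ls, traj, log
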