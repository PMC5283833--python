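"""Trajectory ingestion, cleaning, and discretization into ~5 m steps.

The observational substrate is simultaneous 1 Hz GPS tracking of every
individual in a group. This module regularizes raw fixes onto a common 1 Hz
axis, fills 1-s dropouts by linear interpolation, removes teleportation
outliers, and converts each track into discrete steps by spatial
first-passage: from the current anchor fix, the step ends at the first
subsequent fix at least ``step_length_m`` away. Step-length and turn-angle
samples pooled over those steps define the empirical distributions from
which alternative ("available") locations are drawn for step-selection
modelling.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geo

logger = logging.getLogger(__name__)


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a, 2 * np.pi)
    w = np.where(w > np.pi, w - 2 * np.pi, w)
    return w if w.ndim else float(w)


class InsufficientDataError(ValueError):
    pass


@dataclasses.dataclass
class TrajectorySet:
    """Per-individual positions on a uniform 1 Hz time axis.

    ``xy`` has shape (n_individuals, n_times, 2) with NaN marking missing
    fixes; all coordinates share a single projected CRS in meters.
    """

    ids: list
    times: pd.DatetimeIndex
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.ids), len(self.times), 2):
            raise ValueError("xy shape does not match ids/times")
        if len(self.times) > 1:
            dt = np.diff(self.times.asi8)
            if not np.all(dt == dt[0]) or dt[0] <= 0:
                raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def index_of(self, individual) -> int:
        return self.ids.index(individual)

    def t_index(self, t) -> int:
        """Integer index of timestamp ``t`` on the axis."""
        i = int((pd.Timestamp(t) - self.times[0]) / pd.Timedelta(seconds=1))
        if not 0 <= i < self.n_times:
            raise KeyError(f"timestamp {t} outside trajectory axis")
        return i

    def positions_at(self, t_idx: int) -> np.ndarray:
        """(n_individuals, 2) positions at an integer time index."""
        return self.xy[:, t_idx, :]

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(list(self.ids), self.times, self.xy.copy())

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        n_i, n_t, _ = self.xy.shape
        df = pd.DataFrame(
            {
                "id": np.repeat(self.ids, n_t),
                "timestamp": np.tile(self.times.values, n_i),
                "x": self.xy[:, :, 0].ravel(),
                "y": self.xy[:, :, 1].ravel(),
            }
        )
        return df.dropna(subset=["x", "y"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_trajectories(path_or_frame, crs: Optional[str] = None) -> TrajectorySet:
    """Load a trajectory CSV onto a common 1 Hz axis.

    Expects columns ``id, timestamp, x, y`` (projected meters) or
    ``id, timestamp, lon, lat`` together with a declared UTM zone such as
    ``crs="utm:37N"``. Instants without a fix are marked missing.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame)
    if {"lon", "lat"}.issubset(df.columns) and not {"x", "y"}.issubset(df.columns):
        if crs is None:
            raise ValueError("lon/lat input requires a declared CRS (e.g. 'utm:37N')")
        zone, northern = geo.parse_crs(crs)
        df["x"], df["y"] = geo.lonlat_to_utm(
            df["lon"].to_numpy(), df["lat"].to_numpy(), zone, northern
        )
    missing = {"id", "timestamp", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory input missing columns: {sorted(missing)}")
    ts_col = df["timestamp"]
    if np.issubdtype(ts_col.dtype, np.number):
        df["timestamp"] = pd.to_datetime(ts_col, unit="s")
    else:
        df["timestamp"] = pd.to_datetime(ts_col)
    if df.duplicated(subset=["id", "timestamp"]).any():
        dup = df[df.duplicated(subset=["id", "timestamp"], keep=False)]
        raise ValueError(
            f"duplicate (id, timestamp) rows in input, e.g.\n{dup.head()}"
        )
    ids = sorted(df["id"].unique().tolist())
    t0, t1 = df["timestamp"].min(), df["timestamp"].max()
    times = pd.date_range(t0, t1, freq="1s")
    xy = np.full((len(ids), len(times), 2), np.nan)
    id_pos = {k: i for i, k in enumerate(ids)}
    ti = ((df["timestamp"] - t0) / pd.Timedelta(seconds=1)).to_numpy()
    if not np.allclose(ti, np.round(ti)):
        raise ValueError("timestamps are not aligned to whole seconds")
    ti = np.round(ti).astype(int)
    ii = df["id"].map(id_pos).to_numpy()
    xy[ii, ti, 0] = df["x"].to_numpy()
    xy[ii, ti, 1] = df["y"].to_numpy()
    return TrajectorySet(ids, times, xy)


def fill_gaps(ts: TrajectorySet, max_gap_s: int = 1) -> TrajectorySet:
    """Linearly interpolate missing runs of duration <= ``max_gap_s``.

    Longer gaps are left missing; present fixes are never altered.
    """
    out = ts.copy()
    for i in range(out.n_individuals):
        for d in range(2):
            col = out.xy[i, :, d]
            isnan = np.isnan(col)
            if not isnan.any():
                continue
            # locate missing runs
            edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
            for s, e in zip(edges[::2], edges[1::2]):
                if e - s > max_gap_s:
                    continue
                if s == 0 or e == len(col):
                    continue  # no flanking fix on one side
                x0, x1 = col[s - 1], col[e]
                if np.isnan(x0) or np.isnan(x1):
                    continue
                frac = np.arange(1, e - s + 1) / (e - s + 1)
                col[s:e] = x0 + frac * (x1 - x0)
    return out


def filter_outliers(ts: TrajectorySet, speed_max_ms: float = 8.0) -> TrajectorySet:
    """Mark fixes implying implausible instantaneous speed as missing.

    A fix is removed when the speeds to *both* temporal neighbors exceed
    ``speed_max_ms`` — the signature of a one-sample teleportation. The
    number of removals is logged.
    """
    out = ts.copy()
    removed = 0
    for i in range(out.n_individuals):
        p = out.xy[i]
        d_prev = np.linalg.norm(p[1:] - p[:-1], axis=1)  # speed over 1 s
        bad = np.zeros(len(p), dtype=bool)
        bad[1:-1] = (d_prev[:-1] > speed_max_ms) & (d_prev[1:] > speed_max_ms)
        out.xy[i, bad] = np.nan
        removed += int(bad.sum())
    if removed:
        logger.info("filter_outliers removed %d fixes", removed)
    return out


@dataclasses.dataclass
class StepRecord:
    """One discrete movement step of a focal individual."""

    focal_id: object
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    p_start: np.ndarray
    p_end: np.ndarray
    prev_heading: Optional[float]  # radians CCW from +x; None after a break
    step_length: float
    turn_angle: Optional[float]
    i_start: int = 0  # integer index on the 1 Hz axis
    i_end: int = 0

    @property
    def heading(self) -> float:
        d = self.p_end - self.p_start
        return float(np.arctan2(d[1], d[0]))


def discretize_steps(
    ts: TrajectorySet, focal_id, step_length_m: float = 5.0
) -> list[StepRecord]:
    """First-passage discretization of one individual's track.

    The anchor advances to the first subsequent fix at distance >=
    ``step_length_m``; segments that would span a missing fix are not
    emitted (the anchor restarts after the gap).
    """
    if step_length_m <= 0:
        raise ValueError("step_length_m must be positive")
    i = ts.index_of(focal_id)
    p = ts.xy[i]
    valid = ~np.isnan(p[:, 0])
    steps: list[StepRecord] = []
    prev_heading: Optional[float] = None
    a = 0
    n = len(p)
    while a < n and not valid[a]:
        a += 1
    j = a + 1
    while j < n:
        if not valid[j]:
            # gap: restart beyond it, breaking heading continuity
            while j < n and not valid[j]:
                j += 1
            a = j
            j = a + 1
            prev_heading = None
            continue
        dist = float(np.linalg.norm(p[j] - p[a]))
        if dist >= step_length_m:
            heading = float(np.arctan2(p[j, 1] - p[a, 1], p[j, 0] - p[a, 0]))
            turn = (
                float(wrap_angle(heading - prev_heading))
                if prev_heading is not None
                else None
            )
            steps.append(
                StepRecord(
                    focal_id=focal_id,
                    t_start=ts.times[a],
                    t_end=ts.times[j],
                    p_start=p[a].copy(),
                    p_end=p[j].copy(),
                    prev_heading=prev_heading,
                    step_length=dist,
                    turn_angle=turn,
                    i_start=a,
                    i_end=j,
                )
            )
            prev_heading = heading
            a = j
        j += 1
    return steps


@dataclasses.dataclass
class EmpiricalStepDists:
    """Pooled empirical step-length (m) and turn-angle (rad) samples."""

    step_lengths: np.ndarray
    turn_angles: np.ndarray

    def __post_init__(self) -> None:
        self.step_lengths = np.asarray(self.step_lengths, dtype=float)
        self.turn_angles = np.asarray(self.turn_angles, dtype=float)
        if self.step_lengths.size == 0:
            raise InsufficientDataError("no step-length samples")
        if np.any(self.turn_angles <= -np.pi) or np.any(self.turn_angles > np.pi):
            raise ValueError("turn angles must lie in (-pi, pi]")


def empirical_dists(steps: Sequence[StepRecord]) -> EmpiricalStepDists:
    """Pool step lengths and turn angles over a collection of steps."""
    if len(steps) < 2:
        raise InsufficientDataError(f"need >= 2 steps, got {len(steps)}")
    lengths = np.array([s.step_length for s in steps])
    turns = np.array([s.turn_angle for s in steps if s.turn_angle is not None])
    return EmpiricalStepDists(lengths, turns)


def generate_alternatives(
    step: StepRecord, dists: EmpiricalStepDists, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample K alternative endpoints for one step.

    Each candidate displaces ``p_start`` by an independently resampled
    (length, turn) pair, the turn applied relative to ``prev_heading``
    (uniform heading when no previous step exists).
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    lengths = rng.choice(dists.step_lengths, size=K, replace=True)
    if step.prev_heading is not None and dists.turn_angles.size:
        turns = rng.choice(dists.turn_angles, size=K, replace=True)
        headings = step.prev_heading + turns
    else:
        headings = rng.uniform(-np.pi, np.pi, size=K)
    return step.p_start + np.column_stack(
        (lengths * np.cos(headings), lengths * np.sin(headings))
    )


def steps_to_frame(steps: Sequence[StepRecord]) -> pd.DataFrame:
    """Tabulate steps (one row each) for CSV export."""
    return pd.DataFrame(
        {
            "focal_id": [s.focal_id for s in steps],
            "t_start": [s.t_start for s in steps],
            "t_end": [s.t_end for s in steps],
            "x_start": [s.p_start[0] for s in steps],
            "y_start": [s.p_start[1] for s in steps],
            "x_end": [s.p_end[0] for s in steps],
            "y_end": [s.p_end[1] for s in steps],
            "step_length": [s.step_length for s in steps],
            "turn_angle": [s.turn_angle for s in steps],
        }
    )
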