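"""Social features computed from troop-mates' positions and histories.

Four features describe the social context of a potential location:

* ``social_density`` — fraction of troop mates currently within a radius
  (default 4.25 m) of the location.
* ``recently_used`` — number of *distinct* non-focal individuals that
  occupied the location (came within the occupancy radius) during a
  trailing window, default 4.5 min, the window open at both instants:
  fixes strictly inside (t - window, t) count.
* ``ever_used`` — whether any non-focal individual ever occupied the
  location across the entire dataset (a control for plain physical
  suitability).
* ``visible_fraction`` — fraction of troop mates with an unobstructed
  sight line from the location (vegetation-occlusion test).

"Occupied" is operationalized as a fix within ``occupancy_radius_m``
(default 1.25 m) of the queried point; the radius is configurable since the
underlying field definition leaves the spatial tolerance open.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .landscape import Landscape
from .trajectories import TrajectorySet

DEFAULT_OCCUPANCY_RADIUS_M = 1.25


class OccupancyIndex:
    """Spatial hash over all fixes of a trajectory set.

    Fixes are binned into square cells of side ``cell_size_m`` (the query
    radius); a query inspects the 3x3 cell neighborhood and applies exact
    distance and time filters, so results match a brute-force scan.
    """

    def __init__(self, ts: TrajectorySet, cell_size_m: float = DEFAULT_OCCUPANCY_RADIUS_M):
        if cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        self.cell = float(cell_size_m)
        self.ids = list(ts.ids)
        n_i, n_t, _ = ts.xy.shape
        xs = ts.xy[:, :, 0].ravel()
        ys = ts.xy[:, :, 1].ravel()
        ok = ~np.isnan(xs)
        self.x = xs[ok]
        self.y = ys[ok]
        self.t = np.tile(np.arange(n_t, dtype=np.int64), n_i)[ok]
        self.ind = np.repeat(np.arange(n_i, dtype=np.int32), n_t)[ok]
        cx = np.floor(self.x / self.cell).astype(np.int64)
        cy = np.floor(self.y / self.cell).astype(np.int64)
        key = self._key(cx, cy)
        order = np.lexsort((self.t, key))
        for name in ("x", "y", "t", "ind"):
            setattr(self, name, getattr(self, name)[order])
        key = key[order]
        uniq, starts = np.unique(key, return_index=True)
        ends = np.append(starts[1:], key.size)
        self._cells = {int(k): (int(s), int(e)) for k, s, e in zip(uniq, starts, ends)}

    @staticmethod
    def _key(cx, cy):
        return cx * np.int64(2**31) + cy

    def _gather(self, x: float, y: float):
        """Indices of all fixes in the 3x3 cell neighborhood of (x, y)."""
        cx = int(np.floor(x / self.cell))
        cy = int(np.floor(y / self.cell))
        chunks = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                se = self._cells.get(int(self._key(np.int64(cx + dx), np.int64(cy + dy))))
                if se is not None:
                    chunks.append(np.arange(se[0], se[1]))
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(chunks)

    def recent_count(
        self,
        points,
        t_idx: int,
        window_s: float,
        radius_m: float,
        exclude_ind: int,
    ) -> np.ndarray:
        """Distinct non-focal individuals within ``radius_m`` of each point
        during the open window (t - window, t); times are axis indices."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(points), dtype=float)
        for i, (x, y) in enumerate(points):
            idx = self._gather(x, y)
            if idx.size == 0:
                continue
            sel = (
                (self.t[idx] > t_idx - window_s)
                & (self.t[idx] < t_idx)
                & (self.ind[idx] != exclude_ind)
            )
            idx = idx[sel]
            if idx.size == 0:
                continue
            d2 = (self.x[idx] - x) ** 2 + (self.y[idx] - y) ** 2
            hit = idx[d2 <= radius_m * radius_m]
            out[i] = np.unique(self.ind[hit]).size
        return out

    def ever_used(self, points, radius_m: float, exclude_ind: int) -> np.ndarray:
        """1 iff any non-focal fix ever fell within ``radius_m`` of the point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(points), dtype=float)
        for i, (x, y) in enumerate(points):
            idx = self._gather(x, y)
            if idx.size == 0:
                continue
            idx = idx[self.ind[idx] != exclude_ind]
            if idx.size == 0:
                continue
            d2 = (self.x[idx] - x) ** 2 + (self.y[idx] - y) ** 2
            out[i] = 1.0 if np.any(d2 <= radius_m * radius_m) else 0.0
        return out


def social_density(
    positions_at_t: np.ndarray,
    focal_idx: int,
    candidate,
    radius_m: float = 4.25,
):
    """Fraction of troop mates within ``radius_m`` of candidate point(s).

    ``positions_at_t`` is (n_individuals, 2) with NaN for unknown positions;
    individuals with unknown positions are excluded from the denominator.
    Returns NaN when no non-focal position is known (missing-feature flag).
    """
    pts = np.atleast_2d(np.asarray(candidate, dtype=float))
    scalar = np.asarray(candidate).ndim == 1
    others = np.delete(positions_at_t, focal_idx, axis=0)
    others = others[~np.isnan(others[:, 0])]
    if len(others) == 0:
        res = np.full(len(pts), np.nan)
    else:
        d2 = ((pts[:, None, :] - others[None, :, :]) ** 2).sum(-1)
        res = (d2 <= radius_m * radius_m).sum(axis=1) / len(others)
    return float(res[0]) if scalar else res


def visible_fraction(
    ls: Landscape,
    candidate,
    positions_at_t: np.ndarray,
    focal_idx: int,
    density_threshold: float = 0.5,
):
    """Fraction of troop mates visible from candidate point(s).

    Visibility is the vegetation-occlusion test of the habitat module,
    evaluated by dense sampling along each sight line (<= 1/3 pixel
    spacing) — the same kernel the synthetic generator uses, so generated
    and re-extracted values agree. NaN when no non-focal position is known.
    """
    pts = np.atleast_2d(np.asarray(candidate, dtype=float))
    scalar = np.asarray(candidate).ndim == 1
    others = np.delete(positions_at_t, focal_idx, axis=0)
    others = others[~np.isnan(others[:, 0])]
    out = np.empty(len(pts))
    x0, y0 = ls.origin
    _kernels.visible_fraction_batch(
        ls.vegetation, x0, y0, ls.resolution,
        np.ascontiguousarray(pts[:, 0]), np.ascontiguousarray(pts[:, 1]),
        np.ascontiguousarray(others[:, 0]), np.ascontiguousarray(others[:, 1]),
        float(density_threshold), out,
    )
    return float(out[0]) if scalar else out
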