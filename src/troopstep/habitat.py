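"""Habitat feature values for points and segments against a Landscape.

Feature semantics:

* ``env_density`` — fraction of vegetated (non-ground) area within a radius
  (default 2.5 m) of a location: the mean vegetation density over pixels
  whose centers fall inside the disk.
* ``on_road`` / ``on_path`` — value of the binary mask pixel containing the
  location (half-open pixel convention, so edge points are deterministic).
* ``slope`` — elevation change to a candidate from the previous location,
  bilinear interpolation of the elevation layer.
* ``sleep_dir`` — cosine of the angle between a step vector and the bearing
  to the sleep site: +1 directly toward, -1 directly away.
* ``line_of_sight`` — True iff the segment between two points traverses no
  pixel with vegetation density above threshold (conservative traversal:
  every pixel the segment crosses with positive length is examined).
"""

from __future__ import annotations

import warnings

import numpy as np

from . import _kernels
from .landscape import Landscape


class OutOfExtentError(ValueError):
    pass


def _as_points(p):
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 1
    return np.atleast_2d(p), scalar


def env_density(ls: Landscape, p, radius_m: float = 2.5):
    """Vegetated-area fraction within ``radius_m`` of point(s) ``p``."""
    if radius_m <= 0:
        raise ValueError(f"radius_m must be positive, got {radius_m}")
    pts, scalar = _as_points(p)
    out = np.empty(len(pts))
    x0, y0 = ls.origin
    _kernels.env_density_batch(
        ls.vegetation, x0, y0, ls.resolution,
        np.ascontiguousarray(pts[:, 0]), np.ascontiguousarray(pts[:, 1]),
        float(radius_m), out,
    )
    return float(out[0]) if scalar else out


def _mask_value(ls: Landscape, layer: np.ndarray, p):
    pts, scalar = _as_points(p)
    inside = ls.in_extent(pts[:, 0], pts[:, 1])
    if not np.all(inside):
        raise OutOfExtentError(f"point(s) outside raster extent: {pts[~inside]}")
    out = np.empty(len(pts))
    x0, y0 = ls.origin
    _kernels.mask_at_batch(
        layer, x0, y0, ls.resolution,
        np.ascontiguousarray(pts[:, 0]), np.ascontiguousarray(pts[:, 1]), out,
    )
    out = out.astype(int)
    return int(out[0]) if scalar else out


def on_road(ls: Landscape, p):
    """1 if the point lies on a road pixel, else 0."""
    return _mask_value(ls, ls.roads, p)


def on_path(ls: Landscape, p):
    """1 if the point lies on an animal-path pixel, else 0."""
    return _mask_value(ls, ls.paths, p)


def elevation_at(ls: Landscape, p):
    """Bilinearly interpolated elevation (m) at point(s) ``p``."""
    pts, scalar = _as_points(p)
    out = np.empty(len(pts))
    x0, y0 = ls.origin
    _kernels.bilinear_batch(
        ls.elevation, x0, y0, ls.resolution,
        np.ascontiguousarray(pts[:, 0]), np.ascontiguousarray(pts[:, 1]), out,
    )
    return float(out[0]) if scalar else out


def slope(ls: Landscape, p_from, p_to):
    """Signed elevation change (m) from ``p_from`` to ``p_to``."""
    pts_f, scalar_f = _as_points(p_from)
    pts_t, scalar_t = _as_points(p_to)
    for pts in (pts_f, pts_t):
        if not np.all(ls.in_extent(pts[:, 0], pts[:, 1])):
            raise OutOfExtentError("slope endpoints must lie within the raster")
    res = elevation_at(ls, p_to) - elevation_at(ls, p_from)
    return res


def sleep_dir(p_start, candidate, sleep_site):
    """Directedness of a step toward the sleep site, in [-1, 1]."""
    p_start = np.asarray(p_start, dtype=float)
    candidate = np.asarray(candidate, dtype=float)
    sleep_site = np.asarray(sleep_site, dtype=float)
    v = candidate - p_start
    s = sleep_site - p_start
    sn = np.linalg.norm(s)
    vn = np.linalg.norm(v)
    if sn < 1e-12:
        warnings.warn("step starts at the sleep site; sleep_dir undefined, returning 0")
        return 0.0
    if vn < 1e-12:
        raise ValueError("candidate coincides with p_start")
    return float(np.clip(np.dot(v, s) / (vn * sn), -1.0, 1.0))


def traversed_pixels(ls: Landscape, p1, p2):
    """(rows, cols) of every pixel the open segment p1->p2 crosses with
    positive length, ordered along the segment."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    x0, y0 = ls.origin
    res = ls.resolution
    d = p2 - p1
    length = np.linalg.norm(d)
    if length < 1e-15:
        r, c = ls.world_to_cell(p1[0], p1[1])
        return np.array([r]), np.array([c])
    ts = [0.0, 1.0]
    for axis, o in ((0, x0), (1, y0)):
        if d[axis] != 0.0:
            lo = (p1[axis] - o) / res
            hi = (p2[axis] - o) / res
            k0 = int(np.ceil(min(lo, hi)))
            k1 = int(np.floor(max(lo, hi)))
            if k1 >= k0:
                ks = np.arange(k0, k1 + 1)
                ts.extend(((ks * res + o) - p1[axis]) / d[axis])
    ts = np.unique(np.clip(ts, 0.0, 1.0))
    mid = (ts[:-1] + ts[1:]) / 2.0
    pos_len = np.diff(ts) > 1e-12
    mid = mid[pos_len]
    pts = p1[None, :] + mid[:, None] * d[None, :]
    rows, cols = ls.world_to_cell(pts[:, 0], pts[:, 1])
    nr, nc = ls.shape
    keep = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
    return rows[keep], cols[keep]


def line_of_sight(ls: Landscape, p1, p2, density_threshold: float = 0.5) -> bool:
    """True iff no traversed pixel has vegetation density >= threshold."""
    rows, cols = traversed_pixels(ls, p1, p2)
    return bool(np.all(ls.vegetation[rows, cols] < density_threshold))
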