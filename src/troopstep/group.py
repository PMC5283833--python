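"""Per-minute group-level structure and its habitat/temporal context.

Six troop-level metrics summarize the group each minute:

* **speed** — displacement of the group centroid over the minute (m/min);
* **polarization** — magnitude of the mean unit heading vector over
  individuals (headings from each individual's displacement over the
  minute; near-stationary individuals excluded), 1 = perfect alignment;
* **spread** — mean distance of individuals to the centroid (m);
* **directedness** — straightness of centroid travel over a trailing
  10-minute window: net displacement / summed per-minute path length;
* **elongation** — anisotropy (l1 - l2)/(l1 + l2) of the positional
  covariance eigenvalues, in [0, 1];
* **tilt** — angle in [0, 90] degrees between the group's long axis and
  its direction of travel.

Context labels describe the habitat the group currently occupies (vegetation
fraction and its tertile class, animal-path density, road presence inside
the buffered convex hull of member positions) and the time of day. Context
dependence is quantified two ways: signed differences between within-context
and overall 2-D metric histograms, and all-subsets linear models with Akaike
weights per context predictor.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps
from shapely.geometry import MultiPoint

from .choiceset import DEFAULT_TOD_BINS, TOD_LABELS, tod_of
from .landscape import Landscape
from .trajectories import TrajectorySet

METRICS = ("speed", "polarization", "spread", "directedness", "elongation", "tilt")
METRIC_PAIRS = (("speed", "polarization"), ("spread", "directedness"), ("elongation", "tilt"))
CONTEXT_PREDICTORS = ("env_density", "path_density", "road_present", "time_of_day")

MIN_CONTRIBUTORS = 3
HEADING_MIN_DISP_M = 1.0
DIRECTEDNESS_WINDOW_MIN = 10
HULL_BUFFER_M = 5.0


def _minute_starts(ts: TrajectorySet) -> np.ndarray:
    n_min = (ts.n_times - 1) // 60
    return np.arange(n_min) * 60


def group_metrics(ts: TrajectorySet, window_min: int = DIRECTEDNESS_WINDOW_MIN) -> pd.DataFrame:
    """Six-metric group state per minute (NaN where < 3 contributors)."""
    starts = _minute_starts(ts)
    n_min = len(starts)
    cent = np.full((n_min + 1, 2), np.nan)
    out = pd.DataFrame(
        index=pd.Index(ts.times[starts], name="minute"),
        columns=list(METRICS) + ["n"],
        dtype=float,
    )
    # per-minute centroid over individuals valid at both minute boundaries
    contrib = []
    for k, t0 in enumerate(starts):
        p0 = ts.xy[:, t0, :]
        p1 = ts.xy[:, t0 + 60, :]
        ok = ~np.isnan(p0[:, 0]) & ~np.isnan(p1[:, 0])
        contrib.append(ok)
        if ok.sum() >= MIN_CONTRIBUTORS:
            cent[k] = p0[ok].mean(axis=0)
    # closing centroid of the last minute (for speed of minute n_min-1)
    if n_min > 0:
        t_last = starts[-1] + 60
        p = ts.xy[:, t_last, :]
        ok_last = contrib[-1]
        if ok_last.sum() >= MIN_CONTRIBUTORS:
            cent[n_min] = p[ok_last].mean(axis=0)

    for k, t0 in enumerate(starts):
        ok = contrib[k]
        n_ok = int(ok.sum())
        out.iloc[k, out.columns.get_loc("n")] = n_ok
        if n_ok < MIN_CONTRIBUTORS:
            continue
        p0 = ts.xy[ok, t0, :]
        p1 = ts.xy[ok, t0 + 60, :]
        c0 = p0.mean(axis=0)
        c1 = p1.mean(axis=0)
        disp = c1 - c0
        out.iloc[k, out.columns.get_loc("speed")] = float(np.linalg.norm(disp))

        # polarization from unit headings of displacing individuals
        d = p1 - p0
        dn = np.linalg.norm(d, axis=1)
        moving = dn >= HEADING_MIN_DISP_M
        if moving.sum() >= 1:
            unit = d[moving] / dn[moving, None]
            out.iloc[k, out.columns.get_loc("polarization")] = float(
                np.linalg.norm(unit.mean(axis=0))
            )
        out.iloc[k, out.columns.get_loc("spread")] = float(
            np.linalg.norm(p0 - c0, axis=1).mean()
        )

        # shape from the positional covariance at the minute start
        cov = np.cov(p0.T, bias=True)
        evals, evecs = np.linalg.eigh(cov)
        l1, l2 = evals[-1], evals[0]
        if l1 + l2 > 0:
            out.iloc[k, out.columns.get_loc("elongation")] = float((l1 - l2) / (l1 + l2))
        speed_k = np.linalg.norm(disp)
        if speed_k > 1e-9:
            axis = evecs[:, -1]
            cosang = abs(np.dot(axis, disp / speed_k))
            out.iloc[k, out.columns.get_loc("tilt")] = float(
                np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            )

    # directedness over a forward window of per-minute centroids
    for k in range(n_min):
        k_end = k + window_min
        if k_end > n_min:
            continue
        seg = cent[k : k_end + 1]
        if np.any(np.isnan(seg)):
            continue
        path = float(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum())
        if path > 1e-9:
            out.iloc[k, out.columns.get_loc("directedness")] = float(
                np.linalg.norm(seg[-1] - seg[0]) / path
            )
    return out


def _hull_pixels(ls: Landscape, points: np.ndarray, buffer_m: float = HULL_BUFFER_M):
    """(rows, cols) of landscape pixels whose centers fall in the buffered
    convex hull of the member positions (degenerate hulls become buffered
    lines/points automatically)."""
    hull = MultiPoint([tuple(p) for p in points]).convex_hull.buffer(buffer_m)
    minx, miny, maxx, maxy = hull.bounds
    x0, y0 = ls.origin
    res = ls.resolution
    nr, nc = ls.shape
    c0 = max(int((minx - x0) / res - 1), 0)
    c1 = min(int((maxx - x0) / res + 1), nc - 1)
    r0 = max(int((miny - y0) / res - 1), 0)
    r1 = min(int((maxy - y0) / res + 1), nr - 1)
    if c1 < c0 or r1 < r0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    gx, gy = np.meshgrid(x0 + (cols + 0.5) * res, y0 + (rows + 0.5) * res)
    inside = shapely.contains_xy(hull, gx.ravel(), gy.ravel()).reshape(gx.shape)
    rr, cc = np.nonzero(inside)
    return rows[rr], cols[cc]


def context_labels(
    ts: TrajectorySet,
    ls: Landscape,
    tod_bins=DEFAULT_TOD_BINS,
    buffer_m: float = HULL_BUFFER_M,
) -> pd.DataFrame:
    """Habitat/time context of the group for each minute.

    env_density / path_density are the mean vegetation and path-mask values
    over hull pixels; road_present flags any road pixel in the hull.
    Tertile classes (open / medium / dense) are assigned from the whole-run
    env_density distribution by rank, so the three classes are balanced.
    """
    starts = _minute_starts(ts)
    rows = []
    for t0 in starts:
        p = ts.xy[:, t0, :]
        p = p[~np.isnan(p[:, 0])]
        rec = {
            "minute": ts.times[t0],
            "env_density": np.nan,
            "path_density": np.nan,
            "road_present": np.nan,
            "time_of_day": tod_of(
                ts.times[t0].hour + ts.times[t0].minute / 60.0, tod_bins
            ),
        }
        if len(p) >= MIN_CONTRIBUTORS:
            rr, cc = _hull_pixels(ls, p, buffer_m)
            if rr.size:
                rec["env_density"] = float(ls.vegetation[rr, cc].mean())
                rec["path_density"] = float(ls.paths[rr, cc].mean())
                rec["road_present"] = float(ls.roads[rr, cc].any())
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("minute")
    # rank-based tertiles guarantee near-equal class sizes
    env = df["env_density"]
    ok = env.notna()
    ranks = sps.rankdata(env[ok], method="ordinal")
    classes = np.array(["open", "medium", "dense"], dtype=object)
    df.loc[ok, "env_class"] = classes[((ranks - 1) * 3 / ok.sum()).astype(int)]
    return df


def hist2d_context_diff(
    states: pd.DataFrame,
    metric_pair: tuple[str, str],
    context_mask,
    bins: int = 30,
    pct_limits: tuple[float, float] = (1.0, 99.0),
) -> dict:
    """Signed difference between within-context and overall 2-D histograms.

    Both histograms share bin edges spanning the stated percentile range of
    each metric over *all* data and are normalized to sum to 1, so the
    difference sums to 0; positive cells are over-represented in context.
    """
    mx, my = metric_pair
    for m in metric_pair:
        if m not in states.columns:
            raise KeyError(f"unknown metric {m!r}")
    both = states[[mx, my]].dropna()
    context_mask = pd.Series(np.asarray(context_mask, dtype=bool), index=states.index)
    sub = states.loc[context_mask, [mx, my]].dropna()
    if len(sub) == 0:
        raise ValueError("context contains no minutes with valid metrics")
    ex = np.percentile(both[mx], pct_limits)
    ey = np.percentile(both[my], pct_limits)
    edges_x = np.linspace(ex[0], ex[1], bins + 1)
    edges_y = np.linspace(ey[0], ey[1], bins + 1)
    h_all, _, _ = np.histogram2d(both[mx], both[my], bins=(edges_x, edges_y))
    h_ctx, _, _ = np.histogram2d(sub[mx], sub[my], bins=(edges_x, edges_y))
    h_all = h_all / h_all.sum()
    h_ctx = h_ctx / h_ctx.sum()
    return {
        "diff": h_ctx - h_all,
        "overall": h_all,
        "context": h_ctx,
        "edges": (edges_x, edges_y),
        "n_context": len(sub),
        "n_all": len(both),
    }


def context_linear_models(
    states: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """All-subsets OLS of each group metric on the context predictors.

    The four predictor blocks (vegetation fraction, path density, road
    presence, time of day as a categorical) enter in every combination
    (2^4 models, intercept always included); Akaike weights per predictor
    are summed over models containing it. Effect directions come from the
    full model: the coefficient sign for continuous predictors, and for
    time of day the bins with the largest / smallest fitted level.

    Returns a tidy frame indexed by (metric, predictor) with columns
    ``weight``, ``sign``, ``tod_max``, ``tod_min``.
    """
    import statsmodels.api as sm

    df = states.join(labels, how="inner")
    blocks = {
        "env_density": ["env_density"],
        "path_density": ["path_density"],
        "road_present": ["road_present"],
        "time_of_day": ["tod_midday", "tod_evening"],
    }
    df = df.assign(
        tod_midday=(df["time_of_day"] == 1).astype(float),
        tod_evening=(df["time_of_day"] == 2).astype(float),
    )
    rows = []
    for metric in METRICS:
        cols = ["env_density", "path_density", "road_present", "tod_midday", "tod_evening"]
        d = df[[metric] + cols].dropna()
        y = d[metric].to_numpy()
        if len(d) < 8 or np.std(y) < 1e-12:
            warnings.warn(f"metric {metric!r}: degenerate response; skipping")
            continue
        aics = {}
        for r in range(len(blocks) + 1):
            for combo in itertools.combinations(blocks, r):
                use = [c for b in combo for c in blocks[b]]
                # explicit intercept column: add_constant would skip it when a
                # dummy column is degenerate (e.g. a single-time-of-day run)
                X = np.column_stack([np.ones(len(d))] + [d[c].to_numpy() for c in use])
                fit = sm.OLS(y, X).fit()
                aics[combo] = fit.aic
        amin = min(aics.values())
        w = {c: np.exp(-(a - amin) / 2.0) for c, a in aics.items()}
        tot = sum(w.values())
        w = {c: v / tot for c, v in w.items()}
        full_cols = [c for b in blocks for c in blocks[b]]
        Xf = np.column_stack([np.ones(len(d))] + [d[c].to_numpy() for c in full_cols])
        full = sm.OLS(y, Xf).fit()
        coefs = dict(zip(["const"] + full_cols, full.params))
        tod_levels = {
            0: 0.0,
            1: coefs["tod_midday"],
            2: coefs["tod_evening"],
        }
        for b in blocks:
            weight = min(max(sum(v for c, v in w.items() if b in c), 0.0), 1.0)
            rec = {
                "metric": metric,
                "predictor": b,
                "weight": float(weight),
                "sign": np.nan,
                "tod_max": None,
                "tod_min": None,
            }
            if b == "time_of_day":
                rec["tod_max"] = TOD_LABELS[max(tod_levels, key=tod_levels.get)]
                rec["tod_min"] = TOD_LABELS[min(tod_levels, key=tod_levels.get)]
            else:
                rec["sign"] = float(np.sign(coefs[blocks[b][0]]))
            rows.append(rec)
    return pd.DataFrame(rows).set_index(["metric", "predictor"])
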