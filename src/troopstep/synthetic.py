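"""Synthetic landscapes and model-generated troop trajectories.

The generator inverts the step-selection model: N agents move through a
patchy 2-D landscape, and at each decision draw K+1 candidate endpoints
from a step-length x turn-angle proposal, choosing one with probability
proportional to ``exp(beta_true . features)``. Every decision is logged as
a stratum (all candidates, their feature vectors, the chosen index), so the
fitting machinery can be validated two ways: on the logged features (the
exact generative model) and on features re-extracted from the emitted 1 Hz
trajectories (the full pipeline).

Landscape realism is deliberately schematic: vegetation is thresholded
smoothed noise with a controllable cover fraction and patch scale; roads
are few, long and nearly straight; animal paths are numerous and tortuous;
elevation is smooth; a single sleep site anchors the day's commute through
a sign flip of the sleep-direction coefficient between morning and evening.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _kernels
from .choiceset import RAW_FEATURES, TERMS, ChoiceSet, tod_of, DEFAULT_TOD_BINS
from .landscape import Landscape
from .trajectories import TrajectorySet, wrap_angle


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class LandscapeConfig:
    """Parameters of the synthetic habitat."""

    extent_m: tuple[float, float] = (600.0, 600.0)
    resolution_m: float = 1.0
    vegetation_cover_target: float = 0.30
    vegetation_patch_scale_m: float = 8.0
    n_roads: int = 2
    road_width_m: float = 3.0
    n_paths: int = 30
    path_tortuosity: float = 0.6
    elevation_relief_m: float = 20.0
    sleep_site: Optional[tuple[float, float]] = None  # default: extent center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ConfigurationError(f"extent must be positive, got {self.extent_m}")
        if self.resolution_m <= 0:
            raise ConfigurationError("resolution must be positive")
        if not 0.0 <= self.vegetation_cover_target <= 1.0:
            raise ConfigurationError("vegetation_cover_target must lie in [0, 1]")
        if self.sleep_site is None:
            self.sleep_site = (self.extent_m[0] / 2.0, self.extent_m[1] / 2.0)
        sx, sy = self.sleep_site
        if not (0 <= sx < self.extent_m[0] and 0 <= sy < self.extent_m[1]):
            raise ConfigurationError("sleep_site must lie within the extent")


# Day-commute design: sleep-site coefficient sign-flipped across the day
# (away in the morning, toward in the evening), road following, local
# avoidance of dense vegetation, weak path effect. The radial morning drift
# disperses the troop, so social encounters become sparse later in the day;
# coefficient calibration stays exact because the choice log records the
# features the generative softmax actually used.
DEFAULT_BETA = {
    "env_density": -2.0,
    "social_density": 1.0,
    "sleep_morning": -0.3,
    "sleep_midday": 0.0,
    "sleep_evening": 0.8,
    "road": 1.0,
    "road_x_prev_road": 1.0,
    "recently_used": 0.8,
    "ever_used": 0.5,
    "path": 0.2,
    "path_x_prev_path": 0.2,
    "visible": 0.5,
    "slope": -0.3,
}

COMMUTE_BETA = DEFAULT_BETA

# Home-range foraging design: constant mild attraction to the sleep site
# keeps all agents orbiting a shared core, so troop-mate trails keep
# crossing and the social features (recently-used space above all) stay
# informative indefinitely. This is the design used wherever the analysis
# under test hinges on social-feature variation.
FORAGING_BETA = {
    "env_density": -1.0,
    "social_density": 1.5,
    "sleep_morning": 0.6,
    "sleep_midday": 0.6,
    "sleep_evening": 0.6,
    "road": 0.8,
    "road_x_prev_road": 0.8,
    "recently_used": 2.5,
    "ever_used": 0.6,
    "path": 0.2,
    "path_x_prev_path": 0.2,
    "visible": 0.8,
    "slope": -0.5,
}

DEFAULT_SCALES = {
    "env_density_radius_m": 2.5,
    "social_density_radius_m": 4.25,
    "recently_used_window_s": 270.0,
    "occupancy_radius_m": 1.25,
    "los_density_threshold": 0.5,
}


@dataclasses.dataclass
class AgentConfig:
    """Parameters of the simulated troop and its decision model."""

    n_agents: int = 10
    n_steps: int = 500
    step_length_dist: tuple = ("gamma", {"shape": 5.0, "scale": 1.0})  # mean 5 m
    turn_angle_dist: tuple = ("wrapped_normal", {"sigma": 0.8})
    n_candidates: int = 10  # K alternatives; K+1 candidates per decision
    beta_true: Optional[dict] = None
    scales_true: Optional[dict] = None
    dt_decision_s: int = 20  # one decision per agent every dt seconds
    day_start_hour: float = 6.0
    start_date: str = "2012-08-01"
    start_spread_m: float = 15.0
    tod_bins: tuple = DEFAULT_TOD_BINS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ConfigurationError("n_candidates (K) must be >= 1")
        if self.n_agents < 1 or self.n_steps < 1:
            raise ConfigurationError("n_agents and n_steps must be >= 1")
        if self.dt_decision_s < 1:
            raise ConfigurationError("dt_decision_s must be >= 1 s")
        beta = dict(DEFAULT_BETA) if self.beta_true is None else dict(self.beta_true)
        unknown = set(beta) - set(TERMS)
        if unknown:
            raise ConfigurationError(
                f"beta_true refers to unknown model terms: {sorted(unknown)}"
            )
        self.beta_true = {t: float(beta.get(t, 0.0)) for t in TERMS}
        scales = dict(DEFAULT_SCALES)
        scales.update(self.scales_true or {})
        self.scales_true = scales

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta_true[t] for t in TERMS])


def _polyline_mask(shape, res, pts, half_width_px: int) -> np.ndarray:
    """Rasterize a polyline (sampled at res/2) and dilate to width."""
    nr, nc = shape
    mask = np.zeros(shape, dtype=bool)
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        seg = np.hypot(x2 - x1, y2 - y1)
        n = max(int(seg / (res / 2.0)), 1)
        f = np.linspace(0.0, 1.0, n + 1)
        cs = np.floor((x1 + f * (x2 - x1)) / res).astype(int)
        rs = np.floor((y1 + f * (y2 - y1)) / res).astype(int)
        ok = (rs >= 0) & (rs < nr) & (cs >= 0) & (cs < nc)
        mask[rs[ok], cs[ok]] = True
    if half_width_px > 0:
        yy, xx = np.mgrid[-half_width_px : half_width_px + 1, -half_width_px : half_width_px + 1]
        foot = xx**2 + yy**2 <= (half_width_px + 0.5) ** 2
        mask = ndimage.binary_dilation(mask, structure=foot)
    return mask


def gen_landscape(config: LandscapeConfig) -> Landscape:
    """Generate a co-registered synthetic raster stack. Deterministic given
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    res = config.resolution_m
    w, h = config.extent_m
    nc = int(round(w / res))
    nr = int(round(h / res))

    # roads: few, long, nearly straight polylines crossing the extent
    roads = np.zeros((nr, nc), dtype=bool)
    diag = float(np.hypot(w, h))
    for _ in range(config.n_roads):
        theta = rng.uniform(0, np.pi)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        cy = rng.uniform(0.25 * h, 0.75 * h)
        pts = []
        for sgn in (-1.0, 1.0):
            head = theta if sgn > 0 else theta + np.pi
            x, y = cx, cy
            leg = [(x, y)]
            while 0 <= x < w and 0 <= y < h and len(leg) < diag:
                head += rng.normal(0.0, 0.02)  # nearly straight
                x += 2.0 * np.cos(head)
                y += 2.0 * np.sin(head)
                leg.append((x, y))
            pts = leg[::-1] + pts[1:] if sgn < 0 else pts + leg
        half_w = max(int(round(config.road_width_m / (2 * res))), 0)
        roads |= _polyline_mask((nr, nc), res, pts, half_w)

    # animal paths: many, short, tortuous, single-pixel wide
    paths = np.zeros((nr, nc), dtype=bool)
    for _ in range(config.n_paths):
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        head = rng.uniform(-np.pi, np.pi)
        length = rng.uniform(100.0, 300.0)
        pts = [(x, y)]
        travelled = 0.0
        while travelled < length and 0 <= x < w and 0 <= y < h:
            head += rng.normal(0.0, config.path_tortuosity * 0.1)
            x += 2.0 * np.cos(head)
            y += 2.0 * np.sin(head)
            travelled += 2.0
            pts.append((x, y))
        paths |= _polyline_mask((nr, nc), res, pts, 0)

    # vegetation: thresholded smoothed white noise; open ground on roads/paths
    cover = config.vegetation_cover_target
    if cover <= 0.0:
        veg = np.zeros((nr, nc))
    elif cover >= 1.0:
        veg = np.ones((nr, nc))
    else:
        noise = rng.standard_normal((nr, nc))
        sm = ndimage.gaussian_filter(noise, sigma=config.vegetation_patch_scale_m / res)
        thr = np.quantile(sm, 1.0 - cover)
        veg = (sm >= thr).astype(float)
    veg[roads | paths] = 0.0

    # smooth elevation field scaled to the requested relief
    e = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), sigma=50.0 / res)
    span = e.max() - e.min()
    elevation = (
        (e - e.min()) / span * config.elevation_relief_m
        if span > 0 and config.elevation_relief_m > 0
        else np.zeros((nr, nc))
    )

    return Landscape(
        origin=(0.0, 0.0),
        resolution=res,
        vegetation=veg,
        roads=roads.astype(float),
        paths=paths.astype(float),
        elevation=elevation,
        sleep_site=tuple(config.sleep_site),
    )


def _draw_lengths(rng, dist, size):
    family, params = dist
    if family == "gamma":
        return rng.gamma(params["shape"], params["scale"], size=size)
    if family == "fixed":
        return np.full(size, float(params["value"]))
    if family == "uniform":
        return rng.uniform(params["low"], params["high"], size=size)
    raise ConfigurationError(f"unknown step_length_dist family {family!r}")


def _draw_turns(rng, dist, size):
    family, params = dist
    if family == "wrapped_normal":
        return wrap_angle(rng.normal(0.0, params["sigma"], size=size))
    if family == "uniform":
        return rng.uniform(-np.pi, np.pi, size=size)
    if family == "fixed":
        return np.full(size, float(params["value"]))
    raise ConfigurationError(f"unknown turn_angle_dist family {family!r}")


def simulate_troop(
    landscape: Landscape, agents: AgentConfig
) -> tuple[TrajectorySet, ChoiceSet]:
    """Simulate the troop and log every movement decision.

    Returns the 1 Hz trajectory set (positions linearly interpolated along
    chosen steps) and the choice log: one stratum per decision with the
    exact feature vectors the generative softmax used. Deterministic given
    ``agents.seed``.
    """
    rng = np.random.default_rng(agents.seed)
    n_ag = agents.n_agents
    K1 = agents.n_candidates + 1
    dt = int(agents.dt_decision_s)
    n_rounds = agents.n_steps
    total_s = n_rounds * dt
    ls = landscape
    x0, y0 = ls.origin
    res = ls.resolution
    w, h = ls.extent
    sx, sy = ls.sleep_site
    sc = agents.scales_true
    beta = agents.beta_vector

    # 1 Hz position history, filled as rounds complete
    hx = np.full((n_ag, total_s + 1), np.nan)
    hy = np.full((n_ag, total_s + 1), np.nan)

    # per-agent ever-used coverage at raster resolution
    cov = np.zeros((n_ag, *ls.shape), dtype=np.bool_)

    # initial positions scattered around the sleep site
    P = np.empty((n_ag, 2))
    for a in range(n_ag):
        while True:
            p = np.array([sx, sy]) + rng.normal(0.0, agents.start_spread_m, 2)
            if 0 <= p[0] < w and 0 <= p[1] < h:
                P[a] = p
                break
    heading = rng.uniform(-np.pi, np.pi, n_ag)

    strata_X: list[np.ndarray] = []
    strata_cand: list[np.ndarray] = []
    strata_meta: list[tuple] = []  # (agent, t_s, px, py, prev_road, prev_path, tod, chosen)

    one = np.empty(1)
    for k in range(n_rounds):
        t_now = k * dt
        hour = agents.day_start_hour + t_now / 3600.0
        tod_idx = tod_of(hour, agents.tod_bins)
        N = P.copy()
        new_head = heading.copy()
        order = rng.permutation(n_ag)
        for a in order:
            # draw candidates, resampling any that fall outside the extent
            # (the choice model conditions on the realized candidate set,
            # so rejection keeps the likelihood exact)
            acc_x: list = []
            acc_y: list = []
            got = 0
            for _ in range(12):
                n_draw = 3 * K1
                lengths = _draw_lengths(rng, agents.step_length_dist, n_draw)
                turns = _draw_turns(rng, agents.turn_angle_dist, n_draw)
                heads = heading[a] + turns
                cx = P[a, 0] + lengths * np.cos(heads)
                cy = P[a, 1] + lengths * np.sin(heads)
                inside = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
                acc_x.append(cx[inside])
                acc_y.append(cy[inside])
                got += int(inside.sum())
                if got >= K1:
                    break
            if got < K1:
                continue  # stay put this round (pathological corner)
            cxs = np.ascontiguousarray(np.concatenate(acc_x)[:K1])
            cys = np.ascontiguousarray(np.concatenate(acc_y)[:K1])

            others = np.delete(np.arange(n_ag), a)
            ox = np.ascontiguousarray(P[others, 0])
            oy = np.ascontiguousarray(P[others, 1])
            _kernels.mask_at_batch(ls.roads, x0, y0, res, P[a : a + 1, 0], P[a : a + 1, 1], one)
            prev_road = float(one[0])
            _kernels.mask_at_batch(ls.paths, x0, y0, res, P[a : a + 1, 0], P[a : a + 1, 1], one)
            prev_path = float(one[0])

            X = np.empty((K1, _kernels.N_TERMS))
            _kernels.decision_features(
                cxs, cys, P[a, 0], P[a, 1], prev_road, prev_path, tod_idx,
                ox, oy, hx, hy, t_now, int(sc["recently_used_window_s"]),
                cov, a,
                ls.vegetation, ls.roads, ls.paths, ls.elevation,
                x0, y0, res, x0, y0, res,
                sx, sy,
                sc["env_density_radius_m"], sc["social_density_radius_m"],
                sc["occupancy_radius_m"], sc["los_density_threshold"],
                X,
            )
            u = X @ beta
            u -= u.max()
            p = np.exp(u)
            p /= p.sum()
            chosen = int(np.searchsorted(np.cumsum(p), rng.random()))
            chosen = min(chosen, K1 - 1)

            strata_X.append(X)
            strata_cand.append(np.column_stack((cxs, cys)))
            strata_meta.append((a, t_now, P[a, 0], P[a, 1], prev_road, prev_path, tod_idx, chosen))
            N[a] = (cxs[chosen], cys[chosen])
            new_head[a] = np.arctan2(cys[chosen] - P[a, 1], cxs[chosen] - P[a, 0])

        # emit this round's 1 Hz fixes and update occupancy coverage
        frac = np.arange(dt) / dt
        seg_x = P[:, 0, None] + frac[None, :] * (N[:, 0, None] - P[:, 0, None])
        seg_y = P[:, 1, None] + frac[None, :] * (N[:, 1, None] - P[:, 1, None])
        hx[:, t_now : t_now + dt] = seg_x
        hy[:, t_now : t_now + dt] = seg_y
        for a in range(n_ag):
            _kernels.mark_coverage(
                cov[a], x0, y0, res,
                np.ascontiguousarray(seg_x[a]), np.ascontiguousarray(seg_y[a]),
                sc["occupancy_radius_m"],
            )
        P = N
        heading = new_head
    hx[:, total_s] = P[:, 0]
    hy[:, total_s] = P[:, 1]

    # assemble outputs
    ids = [f"b{a:02d}" for a in range(n_ag)]
    t0 = pd.Timestamp(agents.start_date) + pd.Timedelta(hours=agents.day_start_hour)
    times = pd.date_range(t0, periods=total_s + 1, freq="1s")
    xy = np.stack((hx, hy), axis=-1)
    traj = TrajectorySet(ids, times, xy)

    n = len(strata_meta)
    if n == 0:
        raise RuntimeError("simulation produced no decisions")
    meta = np.array([m[:2] for m in strata_meta])
    Xs = np.stack(strata_X)  # (n, K1, N_TERMS)
    cands = np.stack(strata_cand)
    agent_idx = np.array([m[0] for m in strata_meta], dtype=int)
    raw = {
        "env_density": Xs[:, :, _kernels.I_ENV],
        "social_density": Xs[:, :, _kernels.I_SOCIAL],
        "sleep_dir": (
            Xs[:, :, _kernels.I_SLEEP_MORNING]
            + Xs[:, :, _kernels.I_SLEEP_MIDDAY]
            + Xs[:, :, _kernels.I_SLEEP_EVENING]
        ),
        "road": Xs[:, :, _kernels.I_ROAD],
        "recently_used": Xs[:, :, _kernels.I_RECENT],
        "ever_used": Xs[:, :, _kernels.I_EVER],
        "path": Xs[:, :, _kernels.I_PATH],
        "visible": Xs[:, :, _kernels.I_VISIBLE],
        "slope": Xs[:, :, _kernels.I_SLOPE],
    }
    assert set(raw) == set(RAW_FEATURES)
    choice_log = ChoiceSet(
        focal=np.array([ids[a] for a in agent_idx], dtype=object),
        t=(t0.to_datetime64() + meta[:, 1].astype("timedelta64[s]")).astype("datetime64[s]"),
        p_start=np.array([[m[2], m[3]] for m in strata_meta]),
        cand_xy=cands,
        chosen=np.array([m[7] for m in strata_meta], dtype=int),
        raw=raw,
        prev_road=np.array([m[4] for m in strata_meta]),
        prev_path=np.array([m[5] for m in strata_meta]),
        tod=np.array([m[6] for m in strata_meta], dtype=int),
    )
    return traj, choice_log
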