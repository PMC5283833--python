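"""Numerical kernels shared by the habitat/social feature extractors and the
troop simulator.

All kernels operate on raw arrays so that the generative model and the
analysis pipeline compute *identical* feature values. Compiled with numba
when it is importable; otherwise the plain-Python definitions are used
(correct but slow).

Grid convention: layers are (nrows, ncols) arrays with origin ``(x0, y0)``
at the minimum corner, pixel size ``res``, row index increasing with y and
column index with x. A point belongs to the half-open pixel
``[x0 + c*res, x0 + (c+1)*res) x [y0 + r*res, y0 + (r+1)*res)`` and the
pixel center sits at ``(x0 + (c+0.5)*res, y0 + (r+0.5)*res)``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


# term order of the design matrix; interactions and time-of-day coding
# are applied inside the kernels so generator and refit agree exactly
N_TERMS = 13
(
    I_ENV,
    I_SOCIAL,
    I_SLEEP_MORNING,
    I_SLEEP_MIDDAY,
    I_SLEEP_EVENING,
    I_ROAD,
    I_ROAD_X_PREV,
    I_RECENT,
    I_EVER,
    I_PATH,
    I_PATH_X_PREV,
    I_VISIBLE,
    I_SLOPE,
) = range(N_TERMS)


@njit(cache=False)
def env_density_batch(veg, x0, y0, res, xs, ys, radius, out):
    """Mean vegetation density over pixels whose centers lie within
    ``radius`` of each query point (pixels outside the grid excluded)."""
    nr, nc = veg.shape
    npx = int(radius / res) + 1
    r2 = radius * radius
    for i in range(xs.size):
        x = xs[i]
        y = ys[i]
        c0 = int(np.floor((x - x0) / res))
        r0 = int(np.floor((y - y0) / res))
        acc = 0.0
        cnt = 0
        rlo = r0 - npx
        if rlo < 0:
            rlo = 0
        rhi = r0 + npx + 1
        if rhi > nr:
            rhi = nr
        clo = c0 - npx
        if clo < 0:
            clo = 0
        chi = c0 + npx + 1
        if chi > nc:
            chi = nc
        for r in range(rlo, rhi):
            cy = y0 + (r + 0.5) * res
            dy2 = (cy - y) * (cy - y)
            for c in range(clo, chi):
                cx = x0 + (c + 0.5) * res
                if (cx - x) * (cx - x) + dy2 <= r2:
                    acc += veg[r, c]
                    cnt += 1
        if cnt > 0:
            out[i] = acc / cnt
        else:
            out[i] = np.nan


@njit(cache=False)
def bilinear_batch(grid, x0, y0, res, xs, ys, out):
    """Bilinear interpolation of a cell-centered grid, clamped at edges."""
    nr, nc = grid.shape
    for i in range(xs.size):
        u = (xs[i] - x0) / res - 0.5
        v = (ys[i] - y0) / res - 0.5
        if u < 0.0:
            u = 0.0
        if u > nc - 1.0:
            u = nc - 1.0
        if v < 0.0:
            v = 0.0
        if v > nr - 1.0:
            v = nr - 1.0
        c0 = int(np.floor(u))
        r0 = int(np.floor(v))
        if c0 > nc - 2:
            c0 = nc - 2
        if r0 > nr - 2:
            r0 = nr - 2
        if c0 < 0:
            c0 = 0
        if r0 < 0:
            r0 = 0
        fu = u - c0
        fv = v - r0
        out[i] = (1.0 - fv) * (
            (1.0 - fu) * grid[r0, c0] + fu * grid[r0, c0 + 1]
        ) + fv * ((1.0 - fu) * grid[r0 + 1, c0] + fu * grid[r0 + 1, c0 + 1])


@njit(cache=False)
def mask_at_batch(mask, x0, y0, res, xs, ys, out):
    """Value of the (half-open) pixel containing each point; 0 outside."""
    nr, nc = mask.shape
    for i in range(xs.size):
        c = int(np.floor((xs[i] - x0) / res))
        r = int(np.floor((ys[i] - y0) / res))
        if 0 <= r < nr and 0 <= c < nc:
            out[i] = mask[r, c]
        else:
            out[i] = 0.0


@njit(cache=False)
def los_blocked_sampled(veg, x0, y0, res, ax, ay, bx, by, thr):
    """Sight line blocked test by dense sampling (spacing <= res/3).

    Symmetric in (a, b) by construction: the sample set is a linspace
    including both endpoints.
    """
    nr, nc = veg.shape
    dx = bx - ax
    dy = by - ay
    length = np.sqrt(dx * dx + dy * dy)
    n = int(length / (res / 3.0)) + 1
    for k in range(n + 1):
        f = k / n if n > 0 else 0.0
        x = ax + f * dx
        y = ay + f * dy
        c = int(np.floor((x - x0) / res))
        r = int(np.floor((y - y0) / res))
        if 0 <= r < nr and 0 <= c < nc and veg[r, c] >= thr:
            return True
    return False


@njit(cache=False)
def visible_fraction_batch(veg, x0, y0, res, cxs, cys, ox, oy, thr, out):
    """Per candidate: fraction of other individuals with a clear sight line."""
    n_o = ox.size
    for i in range(cxs.size):
        if n_o == 0:
            out[i] = np.nan
            continue
        vis = 0
        for j in range(n_o):
            if not los_blocked_sampled(
                veg, x0, y0, res, cxs[i], cys[i], ox[j], oy[j], thr
            ):
                vis += 1
        out[i] = vis / n_o


@njit(cache=False)
def recent_count_history(hx, hy, t_now, window, focal, cxs, cys, radius, out):
    """Distinct non-focal individuals with >= 1 fix within ``radius`` of each
    candidate during the open interval (t_now - window, t_now).

    ``hx``/``hy`` are (n_individuals, T) 1 Hz position histories (NaN where
    missing); integer times index columns directly.
    """
    n_ind = hx.shape[0]
    t_lo = t_now - window + 1
    if t_lo < 0:
        t_lo = 0
    r2 = radius * radius
    for i in range(cxs.size):
        cnt = 0
        for a in range(n_ind):
            if a == focal:
                continue
            for tau in range(t_lo, t_now):
                dx = hx[a, tau] - cxs[i]
                if dx != dx:  # NaN
                    continue
                dy = hy[a, tau] - cys[i]
                if dx * dx + dy * dy <= r2:
                    cnt += 1
                    break
        out[i] = cnt


@njit(cache=False)
def ever_used_coverage(cov, cx0, cy0, cres, focal, cxs, cys, out):
    """Binary ever-used lookup against per-individual coverage grids."""
    n_ind, nr, nc = cov.shape
    for i in range(cxs.size):
        c = int(np.floor((cxs[i] - cx0) / cres))
        r = int(np.floor((cys[i] - cy0) / cres))
        val = 0.0
        if 0 <= r < nr and 0 <= c < nc:
            for a in range(n_ind):
                if a != focal and cov[a, r, c]:
                    val = 1.0
                    break
        out[i] = val


@njit(cache=False)
def mark_coverage(cov_a, cx0, cy0, cres, xs, ys, radius):
    """Mark coverage cells whose centers lie within ``radius`` of each fix."""
    nr, nc = cov_a.shape
    npx = int(radius / cres) + 1
    r2 = radius * radius
    for i in range(xs.size):
        x = xs[i]
        if x != x:
            continue
        y = ys[i]
        c0 = int(np.floor((x - cx0) / cres))
        r0 = int(np.floor((y - cy0) / cres))
        for r in range(max(0, r0 - npx), min(nr, r0 + npx + 1)):
            cy = cy0 + (r + 0.5) * cres
            dy2 = (cy - y) * (cy - y)
            for c in range(max(0, c0 - npx), min(nc, c0 + npx + 1)):
                cx = cx0 + (c + 0.5) * cres
                if (cx - x) * (cx - x) + dy2 <= r2:
                    cov_a[r, c] = True


@njit(cache=False)
def decision_features(
    cxs,
    cys,
    px,
    py,
    prev_road,
    prev_path,
    tod_idx,
    ox,
    oy,
    hx,
    hy,
    t_now,
    window,
    cov,
    focal,
    veg,
    roads,
    paths,
    elev,
    x0,
    y0,
    res,
    cx0,
    cy0,
    cres,
    sx,
    sy,
    env_radius,
    social_radius,
    occ_radius,
    los_thr,
    X,
):
    """Full design-matrix rows for one movement decision.

    Fills ``X`` with shape (n_candidates, N_TERMS). ``ox``/``oy`` are the
    current positions of the non-focal individuals (already filtered).
    """
    m = cxs.size
    n_o = ox.size

    env = np.empty(m)
    env_density_batch(veg, x0, y0, res, cxs, cys, env_radius, env)
    road = np.empty(m)
    mask_at_batch(roads, x0, y0, res, cxs, cys, road)
    path = np.empty(m)
    mask_at_batch(paths, x0, y0, res, cxs, cys, path)
    elev_c = np.empty(m)
    bilinear_batch(elev, x0, y0, res, cxs, cys, elev_c)
    e0 = np.empty(1)
    xs0 = np.empty(1)
    ys0 = np.empty(1)
    xs0[0] = px
    ys0[0] = py
    bilinear_batch(elev, x0, y0, res, xs0, ys0, e0)
    recent = np.empty(m)
    recent_count_history(hx, hy, t_now, window, focal, cxs, cys, occ_radius, recent)
    ever = np.empty(m)
    ever_used_coverage(cov, cx0, cy0, cres, focal, cxs, cys, ever)
    vis = np.empty(m)
    visible_fraction_batch(veg, x0, y0, res, cxs, cys, ox, oy, los_thr, vis)

    # bearing to the sleep site from the step start
    dsx = sx - px
    dsy = sy - py
    dn = np.sqrt(dsx * dsx + dsy * dsy)
    sr2 = social_radius * social_radius
    for i in range(m):
        for k in range(N_TERMS):
            X[i, k] = 0.0
        X[i, I_ENV] = env[i]
        # social density: fraction of non-focal individuals within radius
        if n_o > 0:
            cnt = 0
            for j in range(n_o):
                dx = ox[j] - cxs[i]
                dy = oy[j] - cys[i]
                if dx * dx + dy * dy <= sr2:
                    cnt += 1
            X[i, I_SOCIAL] = cnt / n_o
        else:
            X[i, I_SOCIAL] = np.nan
        vx = cxs[i] - px
        vy = cys[i] - py
        vn = np.sqrt(vx * vx + vy * vy)
        if dn > 1e-12 and vn > 1e-12:
            sdir = (vx * dsx + vy * dsy) / (vn * dn)
            if sdir > 1.0:
                sdir = 1.0
            if sdir < -1.0:
                sdir = -1.0
        else:
            sdir = 0.0
        X[i, I_SLEEP_MORNING + tod_idx] = sdir
        X[i, I_ROAD] = road[i]
        X[i, I_ROAD_X_PREV] = road[i] * prev_road
        X[i, I_RECENT] = recent[i]
        X[i, I_EVER] = ever[i]
        X[i, I_PATH] = path[i]
        X[i, I_PATH_X_PREV] = path[i] * prev_path
        X[i, I_VISIBLE] = vis[i]
        X[i, I_SLOPE] = elev_c[i] - e0[0]
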