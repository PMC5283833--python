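"""Step-selection model fitting and multi-model inference.

The central statistic is the conditional (multinomial) logit over movement
strata: for stratum s with candidates x_1..x_m and chosen candidate c,

    logL(beta) = sum_s [ beta . x_c  -  log sum_j exp(beta . x_j) ] .

Intercepts cancel within strata, so only feature *differences* among the
candidates of a stratum are informative. :class:`StepSelectionModel` fits
beta by second-order (Newton) ascent from beta = 0; the
:class:`StepSelectionResults` object carries the estimates, their standard
errors from the observed information, log-likelihood, AIC and convergence
diagnostics, statsmodels-style.

The module also implements the surrounding inference machinery: assembling
choice sets from discretized steps, profile-likelihood inference of the
spatial/temporal scales of scale-dependent features, all-subsets Akaike
feature weights, blocked cross-validated log loss, and per-pixel preference
landscapes implied by a fit.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels, habitat, social
from .choiceset import (
    BLOCKS,
    BLOCK_NAMES,
    HABITAT_BLOCKS,
    SOCIAL_BLOCKS,
    RAW_FEATURES,
    TERMS,
    ChoiceSet,
    DEFAULT_TOD_BINS,
    tod_of,
)
from .landscape import Landscape
from .synthetic import DEFAULT_SCALES
from .trajectories import (
    EmpiricalStepDists,
    InsufficientDataError,
    StepRecord,
    TrajectorySet,
    generate_alternatives,
)

logger = logging.getLogger(__name__)

SCALE_FEATURES = ("env_density", "social_density", "recently_used")


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _ll(beta, X, chosen):
    u = X @ beta
    umax = u.max(axis=1)
    lse = umax + np.log(np.exp(u - umax[:, None]).sum(axis=1))
    return float((u[np.arange(len(chosen)), chosen] - lse).sum())


def _ll_grad_hess(beta, X, chosen):
    n, m, p = X.shape
    u = X @ beta
    umax = u.max(axis=1)
    eu = np.exp(u - umax[:, None])
    denom = eu.sum(axis=1)
    P = eu / denom[:, None]
    ll = float((u[np.arange(n), chosen] - umax - np.log(denom)).sum())
    xbar = (P[:, :, None] * X).sum(axis=1)
    grad = (X[np.arange(n), chosen] - xbar).sum(axis=0)
    W = X.reshape(n * m, p) * np.sqrt(P).reshape(n * m)[:, None]
    hess = -(W.T @ W - xbar.T @ xbar)
    return ll, grad, hess


def clogit_loglik(beta, cs: ChoiceSet, blocks: Optional[Sequence[str]] = None) -> float:
    """Conditional-logit log-likelihood of ``beta`` on a choice set."""
    X, terms = cs.design_matrix(blocks)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(terms),):
        raise ValueError(f"beta must have {len(terms)} entries ({terms})")
    return _ll(beta, X, chosen=cs.chosen)


class StepSelectionModel:
    """Conditional-logit step-selection model.

    Parameters
    ----------
    X : ndarray (n_strata, n_candidates, n_terms)
        Design matrix (one feature-vector per candidate per stratum).
    chosen : ndarray (n_strata,)
        Index of the chosen candidate in each stratum.
    terms : sequence of str
        Term names (columns of X).
    standardize : bool
        Divide each term by its pooled standard deviation before fitting
        (coefficients then per-SD; conditional logit is location
        invariant, so no centering is needed).
    ridge : float
        Optional L2 penalty, used as a fallback under complete separation.
    """

    def __init__(
        self,
        X,
        chosen,
        terms,
        standardize: bool = False,
        ridge: float = 0.0,
        check_rank: bool = True,
    ):
        self.check_rank = check_rank
        self.X = np.asarray(X, dtype=float)
        self.chosen = np.asarray(chosen, dtype=int)
        self.terms = list(terms)
        if self.X.ndim != 3 or self.X.shape[2] != len(self.terms):
            raise ValueError("X must be (n, m, p) matching terms")
        if self.X.shape[0] < 1:
            raise InsufficientDataError("need at least one stratum")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite values")
        self.ridge = float(ridge)
        self.scale_ = np.ones(len(self.terms))
        if standardize:
            sd = self.X.reshape(-1, len(self.terms)).std(axis=0)
            sd[sd == 0] = 1.0
            self.scale_ = sd
            self.X = self.X / sd
        self.standardize = standardize

    @classmethod
    def from_choice_set(
        cls,
        cs: ChoiceSet,
        blocks: Optional[Sequence[str]] = None,
        **kwargs,
    ) -> "StepSelectionModel":
        X, terms = cs.design_matrix(blocks)
        return cls(X, cs.chosen, terms, **kwargs)

    @property
    def n_strata(self) -> int:
        return self.X.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.X.shape[1]

    def loglik(self, beta) -> float:
        # beta on the raw-feature scale; X is stored divided by scale_
        return _ll(np.asarray(beta, dtype=float) * self.scale_, self.X, self.chosen)

    def _rank_deficient(self) -> bool:
        n, m, p = self.X.shape
        Xc = self.X - self.X.mean(axis=1, keepdims=True)
        s = np.linalg.svd(Xc.reshape(n * m, p), compute_uv=False)
        return bool(s.size == 0 or s[-1] < 1e-8 * max(s[0], 1.0))

    def fit(
        self,
        maxiter: int = 100,
        gtol: float = 1e-8,
        start: Optional[np.ndarray] = None,
    ) -> "StepSelectionResults":
        n, m, p = self.X.shape
        beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
        collinear = self._rank_deficient() if self.check_rank else False
        separation = False
        ll, grad, hess = _ll_grad_hess(beta, self.X, self.chosen)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            if np.max(np.abs(grad)) < gtol:
                converged = True
                break
            A = -hess + self.ridge * np.eye(p)
            g = grad - self.ridge * beta
            try:
                step = np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(A, g, rcond=None)[0]
                collinear = True
            # backtracking safeguard
            new_beta = beta + step
            new_ll = _ll(new_beta, self.X, self.chosen) - 0.5 * self.ridge * new_beta @ new_beta
            ll_pen = ll - 0.5 * self.ridge * beta @ beta
            shrink = 0
            while new_ll < ll_pen - 1e-12 and shrink < 30:
                step *= 0.5
                new_beta = beta + step
                new_ll = _ll(new_beta, self.X, self.chosen) - 0.5 * self.ridge * new_beta @ new_beta
                shrink += 1
            beta = new_beta
            if np.max(np.abs(beta)) > 50.0 and self.ridge == 0.0:
                separation = True
            ll, grad, hess = _ll_grad_hess(beta, self.X, self.chosen)
        else:
            it = maxiter
        if not converged and np.max(np.abs(grad)) < gtol:
            converged = True
        A = -hess + self.ridge * np.eye(p)
        try:
            cov = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(A)
            collinear = True
        # report on the raw-feature scale
        beta_out = beta / self.scale_
        cov_out = cov / np.outer(self.scale_, self.scale_)
        ll0 = -n * np.log(m)
        return StepSelectionResults(
            model=self,
            params=pd.Series(beta_out, index=self.terms),
            cov_params_arr=cov_out,
            llf=ll,
            llnull=float(ll0),
            converged=converged,
            separation=separation,
            collinear=collinear,
            niter=it,
        )


@dataclasses.dataclass
class StepSelectionResults:
    """Fit results: estimates, uncertainty and diagnostics."""

    model: StepSelectionModel
    params: pd.Series
    cov_params_arr: np.ndarray
    llf: float
    llnull: float
    converged: bool
    separation: bool
    collinear: bool
    niter: int

    @property
    def terms(self):
        return list(self.params.index)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self.cov_params_arr), 0, None)), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov_params_arr, index=self.params.index, columns=self.params.index)

    @property
    def df_model(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.df_model - 2.0 * self.llf

    @property
    def aicc(self) -> float:
        n = self.model.n_strata
        k = self.df_model
        denom = max(n - k - 1, 1)
        return self.aic + 2.0 * k * (k + 1) / denom

    @property
    def zvalues(self) -> pd.Series:
        bse = self.bse.copy()
        bse[bse < 1e-10] = np.nan  # unidentified terms (degenerate columns)
        return self.params / bse

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def predict_probs(self, X: Optional[np.ndarray] = None) -> np.ndarray:
        """Within-stratum choice probabilities under the fitted model."""
        if X is None:
            X = self.model.X * self.model.scale_
        u = X @ self.params.to_numpy()
        u = u - u.max(axis=1, keepdims=True)
        eu = np.exp(u)
        return eu / eu.sum(axis=1, keepdims=True)

    def summary(self) -> str:
        ci = self.conf_int()
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.zvalues,
                "[0.025": ci["lower"],
                "0.975]": ci["upper"],
            }
        )
        flags = []
        if not self.converged:
            flags.append("NOT CONVERGED")
        if self.separation:
            flags.append("possible complete separation")
        if self.collinear:
            flags.append("rank-deficient design")
        lines = [
            "Step Selection Model (conditional logit)",
            "=" * 72,
            f"No. strata: {self.model.n_strata}    candidates/stratum: {self.model.n_candidates}",
            f"Log-likelihood: {self.llf:.3f}    LL(null): {self.llnull:.3f}",
            f"AIC: {self.aic:.3f}    iterations: {self.niter}",
        ]
        if flags:
            lines.append("WARNING: " + "; ".join(flags))
        lines.append("-" * 72)
        lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        lines.append("=" * 72)
        return "\n".join(lines)


def fit_clogit(
    cs: ChoiceSet,
    feature_subset: Optional[Sequence[str]] = None,
    standardize: bool = False,
    ridge: float = 0.0,
    **fit_kwargs,
) -> StepSelectionResults:
    """Fit a conditional-logit SSF on a choice set.

    ``feature_subset`` selects feature blocks (interaction terms travel
    with their main effect); default is all blocks.
    """
    model = StepSelectionModel.from_choice_set(
        cs, blocks=feature_subset, standardize=standardize, ridge=ridge
    )
    return model.fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# feature extraction for analysis-side choice sets
# ---------------------------------------------------------------------------

class FeatureContext:
    """Bundles everything needed to evaluate candidate features.

    Holds the landscape, the trajectory set (for social features), the
    feature scales and the time-of-day bin boundaries. The occupancy index
    is built lazily on first use.
    """

    def __init__(
        self,
        landscape: Landscape,
        trajectories: TrajectorySet,
        scales: Optional[dict] = None,
        tod_bins=DEFAULT_TOD_BINS,
    ):
        self.ls = landscape
        self.ts = trajectories
        self.scales = dict(DEFAULT_SCALES)
        self.scales.update(scales or {})
        for key, val in self.scales.items():
            if key.endswith(("_m", "_s")) and val <= 0:
                raise ValueError(f"scale {key} must be positive, got {val}")
        self.tod_bins = tod_bins
        self._occ: Optional[social.OccupancyIndex] = None

    @property
    def occupancy(self) -> social.OccupancyIndex:
        if self._occ is None:
            self._occ = social.OccupancyIndex(
                self.ts, cell_size_m=self.scales["occupancy_radius_m"]
            )
        return self._occ

    def hour_of(self, t) -> float:
        t = pd.Timestamp(t)
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    def raw_features(self, focal_id, i_t: int, p_start, cand: np.ndarray):
        """Raw feature arrays for the candidates of one stratum.

        Returns (raw, prev_road, prev_path, tod) or None when the stratum
        must be dropped (off-raster candidate or no known troop mates).
        """
        ls = self.ls
        sc = self.scales
        cand = np.asarray(cand, dtype=float)
        p_start = np.asarray(p_start, dtype=float)
        if not np.all(ls.in_extent(cand[:, 0], cand[:, 1])) or not np.all(
            ls.in_extent(p_start[0:1], p_start[1:2])
        ):
            return None
        focal_idx = self.ts.index_of(focal_id)
        pos = self.ts.positions_at(i_t)
        env = habitat.env_density(ls, cand, sc["env_density_radius_m"])
        road = habitat.on_road(ls, cand).astype(float)
        path = habitat.on_path(ls, cand).astype(float)
        slope = habitat.slope(ls, np.tile(p_start, (len(cand), 1)), cand)
        sdir = np.array([habitat.sleep_dir(p_start, c, ls.sleep_site) for c in cand])
        soc = social.social_density(pos, focal_idx, cand, sc["social_density_radius_m"])
        vis = social.visible_fraction(
            ls, cand, pos, focal_idx, sc["los_density_threshold"]
        )
        recent = self.occupancy.recent_count(
            cand,
            i_t,
            sc["recently_used_window_s"],
            sc["occupancy_radius_m"],
            exclude_ind=focal_idx,
        )
        ever = self.occupancy.ever_used(
            cand, sc["occupancy_radius_m"], exclude_ind=focal_idx
        )
        raw = {
            "env_density": env,
            "social_density": np.atleast_1d(soc),
            "sleep_dir": sdir,
            "road": road,
            "recently_used": recent,
            "ever_used": ever,
            "path": path,
            "visible": np.atleast_1d(vis),
            "slope": np.atleast_1d(slope),
        }
        if any(np.any(~np.isfinite(v)) for v in raw.values()):
            return None
        prev_road = float(habitat.on_road(ls, p_start))
        prev_path = float(habitat.on_path(ls, p_start))
        tod = tod_of(self.hour_of(self.ts.times[i_t]), self.tod_bins)
        return raw, prev_road, prev_path, tod


def build_choice_sets(
    steps: Sequence[StepRecord],
    dists: EmpiricalStepDists,
    K: int,
    ctx: FeatureContext,
    rng: np.random.Generator,
) -> ChoiceSet:
    """Assemble a choice set: each observed step paired with K sampled
    alternatives, features computed for every candidate.

    Strata containing an off-raster candidate or lacking known troop-mate
    positions are dropped (and counted in ``n_dropped``).
    """
    if len(steps) == 0:
        raise InsufficientDataError("no steps to build choice sets from")
    if K < 1:
        raise ValueError("K must be >= 1")
    recs = []
    n_dropped = 0
    for step in steps:
        alts = generate_alternatives(step, dists, K, rng)
        cand = np.vstack((step.p_end[None, :], alts))
        out = ctx.raw_features(step.focal_id, step.i_start, step.p_start, cand)
        if out is None:
            n_dropped += 1
            continue
        raw, prev_road, prev_path, tod = out
        recs.append((step, cand, raw, prev_road, prev_path, tod))
    if not recs:
        raise InsufficientDataError("all strata were dropped during assembly")
    if n_dropped:
        logger.info("build_choice_sets dropped %d strata", n_dropped)
    n = len(recs)
    m = K + 1
    return ChoiceSet(
        focal=np.array([r[0].focal_id for r in recs], dtype=object),
        t=np.array([np.datetime64(r[0].t_start, "s") for r in recs]),
        p_start=np.array([r[0].p_start for r in recs]),
        cand_xy=np.stack([r[1] for r in recs]),
        chosen=np.zeros(n, dtype=int),  # true endpoint listed first
        raw={k: np.stack([r[2][k] for r in recs]) for k in RAW_FEATURES},
        prev_road=np.array([r[3] for r in recs]),
        prev_path=np.array([r[4] for r in recs]),
        tod=np.array([r[5] for r in recs], dtype=int),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# scale inference
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScaleProfile:
    """Profile log-likelihood of a feature over a grid of candidate scales."""

    feature: str
    grid: np.ndarray
    loglik: np.ndarray
    best_scale: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"scale": self.grid, "loglik": self.loglik})


def _recompute_scaled_feature(
    cs: ChoiceSet, feature: str, scale: float, ctx: FeatureContext
) -> np.ndarray:
    """Rebuild one scale-dependent raw feature column at a given scale."""
    n, m, _ = cs.cand_xy.shape
    out = np.empty((n, m))
    if feature == "env_density":
        pts = cs.cand_xy.reshape(-1, 2)
        out[:] = habitat.env_density(ctx.ls, pts, scale).reshape(n, m)
        return out
    for i in range(n):
        i_t = ctx.ts.t_index(cs.t[i])
        focal_idx = ctx.ts.index_of(cs.focal[i])
        if feature == "recently_used":
            out[i] = ctx.occupancy.recent_count(
                cs.cand_xy[i],
                i_t,
                scale,
                ctx.scales["occupancy_radius_m"],
                exclude_ind=focal_idx,
            )
        elif feature == "social_density":
            pos = ctx.ts.positions_at(i_t)
            out[i] = social.social_density(pos, focal_idx, cs.cand_xy[i], scale)
        else:
            raise KeyError(f"feature {feature!r} has no scale parameter")
    return out


def infer_scale(
    cs: ChoiceSet, feature: str, grid: Sequence[float], ctx: FeatureContext
) -> ScaleProfile:
    """Maximum-likelihood scale of a scale-dependent feature.

    For each candidate scale the feature column is rebuilt and a
    single-feature conditional logit fitted; the profile of maximized
    log-likelihoods over the grid identifies the best-supported scale.
    """
    if feature not in SCALE_FEATURES:
        raise KeyError(f"scale inference supports {SCALE_FEATURES}, got {feature!r}")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("scale grid is empty")
    lls = np.full(grid.size, np.nan)
    for g, scale in enumerate(grid):
        col = _recompute_scaled_feature(cs, feature, scale, ctx)
        model = StepSelectionModel(col[:, :, None], cs.chosen, [feature])
        res = model.fit()
        if res.converged:
            lls[g] = res.llf
    if np.all(np.isnan(lls)):
        raise RuntimeError(f"all scale fits failed for {feature}")
    best = float(grid[np.nanargmax(lls)])
    return ScaleProfile(feature=feature, grid=grid, loglik=lls, best_scale=best)


# ---------------------------------------------------------------------------
# multi-model inference
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FeatureWeights:
    """Per-individual Akaike feature weights and their medians."""

    per_individual: pd.DataFrame  # index: focal id, columns: feature blocks
    medians: pd.Series

    def ranking(self) -> pd.Series:
        """Feature blocks sorted by decreasing median weight."""
        return self.medians.sort_values(ascending=False)


def _subset_weights(cs: ChoiceSet, features: Sequence[str], use_aicc: bool) -> pd.Series:
    """Akaike feature weights for one individual via all-subsets fits."""
    X_full, terms_full = cs.design_matrix(features)
    col_of = {t: j for j, t in enumerate(terms_full)}
    n_feat = len(features)
    # a subset of a full-rank design is full-rank: check once, not 2^F times
    full_model = StepSelectionModel(X_full, cs.chosen, terms_full)
    full_ok = not full_model._rank_deficient()
    full_start = None
    if full_ok:
        full_res = full_model.fit()
        if full_res.converged:
            full_start = full_res.params.to_numpy()
    aics = []
    masks = []
    excluded = 0
    for bits in range(2 ** n_feat):
        sub = [features[i] for i in range(n_feat) if bits >> i & 1]
        cols = [col_of[t] for t in terms_full if any(t in BLOCKS[b] for b in sub)]
        if cols:
            model = StepSelectionModel(
                X_full[:, :, cols],
                cs.chosen,
                [terms_full[c] for c in cols],
                check_rank=not full_ok,
            )
            # warm-start at the full-model coefficients of the retained terms;
            # the looser tolerance still gives log-likelihoods far beyond the
            # precision AIC weights need
            start = full_start[cols] if full_start is not None else None
            res = model.fit(start=start, gtol=1e-6)
            if not res.converged:
                excluded += 1
                continue
            aic = res.aicc if use_aicc else res.aic
        else:
            ll0 = -cs.n_strata * np.log(cs.n_candidates)
            aic = -2.0 * ll0
        aics.append(aic)
        masks.append(bits)
    if excluded:
        warnings.warn(
            f"{excluded} non-converged subset models excluded from Akaike weights"
        )
    aics = np.asarray(aics)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    fw = {}
    for i, b in enumerate(features):
        tot = float(sum(wm for wm, bits in zip(w, masks) if bits >> i & 1))
        fw[b] = min(max(tot, 0.0), 1.0)  # guard float round-off at saturation
    return pd.Series(fw)


def all_subsets_aic(
    cs: ChoiceSet,
    features: Optional[Sequence[str]] = None,
    use_aicc: bool = False,
) -> FeatureWeights:
    """All-subsets multi-model inference: per-feature Akaike weights.

    Every combination of feature blocks is fitted; the Akaike weight of a
    feature is the summed weight of all models containing it, computed per
    individual, with medians across individuals reported.
    """
    features = list(features) if features is not None else list(BLOCK_NAMES)
    if len(features) > 12:
        raise ValueError("all-subsets inference limited to <= 12 feature blocks")
    rows = {}
    for fid in cs.focal_ids:
        rows[fid] = _subset_weights(cs.for_focal(fid), features, use_aicc)
    per_ind = pd.DataFrame(rows).T
    per_ind = per_ind[features]
    return FeatureWeights(per_individual=per_ind, medians=per_ind.median(axis=0))


# ---------------------------------------------------------------------------
# out-of-sample predictive comparison
# ---------------------------------------------------------------------------

MODEL_CLASSES = {
    "null": None,
    "habitat_only": HABITAT_BLOCKS,
    "social_only": SOCIAL_BLOCKS,
    "full": BLOCK_NAMES,
}


def oos_log_loss(
    cs: ChoiceSet,
    n_folds: int = 3,
    classes: Sequence[str] = ("null", "habitat_only", "social_only", "full"),
) -> dict:
    """Cross-validated negative log loss per model class.

    Folds are contiguous in time (respecting temporal autocorrelation);
    the null model assigns uniform probability, scoring exactly
    log(n_candidates) per stratum.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    order = np.argsort(cs.t, kind="stable")
    folds = np.array_split(order, n_folds)
    if any(len(f) == 0 for f in folds):
        raise ValueError("a fold contains no strata")
    m = cs.n_candidates
    out = {}
    for name in classes:
        blocks = MODEL_CLASSES[name]
        if blocks is None:
            out[name] = float(np.log(m))
            continue
        losses = []
        for f in range(n_folds):
            test_idx = folds[f]
            train_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            res = fit_clogit(cs.subset(train_idx), feature_subset=blocks)
            test = cs.subset(test_idx)
            Xt, _ = test.design_matrix(blocks)
            u = Xt @ res.params.to_numpy()
            u = u - u.max(axis=1, keepdims=True)
            p = np.exp(u)
            p /= p.sum(axis=1, keepdims=True)
            losses.append(-np.log(p[np.arange(len(test.chosen)), test.chosen]))
        out[name] = float(np.concatenate(losses).mean())
    return out


# ---------------------------------------------------------------------------
# preference landscapes
# ---------------------------------------------------------------------------

def preference_landscape(
    results: StepSelectionResults,
    ctx: FeatureContext,
    t,
    focal_id,
    p_start,
    extent: Optional[tuple] = None,
    resolution: Optional[float] = None,
    normalize: bool = False,
) -> dict:
    """Per-feature and combined relative-selection rasters around a step.

    For every pixel center q the per-feature panel holds
    ``exp(beta_block . x_block(q))`` with features computed exactly as for
    choice sets; combined panels multiply the habitat, social, or all
    blocks. With ``normalize=True`` each panel is scaled to [0, 1] for
    rendering (the unnormalized combined panel is the product of the
    unnormalized per-feature panels).
    """
    ls = ctx.ls
    res_m = resolution or ls.resolution
    if extent is None:
        x0, y0 = ls.origin
        w, h = ls.extent
        extent = (x0, x0 + w, y0, y0 + h)
    xlo, xhi, ylo, yhi = extent
    xs = np.arange(xlo + res_m / 2, xhi, res_m)
    ys = np.arange(ylo + res_m / 2, yhi, res_m)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack((gx.ravel(), gy.ravel()))
    i_t = ctx.ts.t_index(t)
    out_shape = gx.shape

    # raw features with the query pixel as candidate endpoint
    out = ctx.raw_features(focal_id, i_t, np.asarray(p_start, dtype=float), pts)
    if out is None:
        raise ValueError("preference landscape extent leaves the raster or troop unknown")
    raw, prev_road, prev_path, tod = out
    pseudo = ChoiceSet(
        focal=np.array([focal_id], dtype=object),
        t=np.array([np.datetime64(pd.Timestamp(t), "s")]),
        p_start=np.asarray(p_start, dtype=float)[None, :],
        cand_xy=pts[None, :, :],
        chosen=np.array([0]),
        raw={k: np.asarray(v)[None, :] for k, v in raw.items()},
        prev_road=np.array([prev_road]),
        prev_path=np.array([prev_path]),
        tod=np.array([tod], dtype=int),
    )
    beta = results.params
    fitted_blocks = [b for b in BLOCK_NAMES if any(t_ in beta.index for t_ in BLOCKS[b])]
    panels = {}
    logs = {}
    for b in fitted_blocks:
        acc = np.zeros(len(pts))
        for term in BLOCKS[b]:
            if term in beta.index:
                acc += beta[term] * pseudo._term_column(term)[0]
        logs[b] = acc
        panels[b] = np.exp(acc).reshape(out_shape)
    for name, group in (
        ("habitat", HABITAT_BLOCKS),
        ("social", SOCIAL_BLOCKS),
        ("all", fitted_blocks),
    ):
        acc = np.zeros(len(pts))
        for b in group:
            if b in logs:
                acc += logs[b]
        panels[name] = np.exp(acc).reshape(out_shape)
    if normalize:
        for k, v in panels.items():
            vmax, vmin = v.max(), v.min()
            panels[k] = (v - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(v)
    panels["_meta"] = {"xs": xs, "ys": ys, "extent": extent, "tod": tod}
    return panels
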