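"""Assumption-light paired-choice analysis.

Complementary to model fitting: each observed step is paired with exactly
one sampled alternative, one of the two endpoints is randomly labelled
*location 1*, and the probability that location 1 was the truly chosen
location is estimated as a function of the difference in the number of
troop mates that recently occupied each location. Conditioning the curve
on road context or on the difference in sleep-site directedness exposes
how habitat biases trade off against the social following tendency,
without the parametric combination rule the conditional logit assumes.
Uncertainty is summarized by exact (Clopper-Pearson) binomial intervals.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .choiceset import ChoiceSet

DEFAULT_DN_RANGE = 5  # integer bins -5..5 with pooled tails
DEFAULT_MIN_BIN_N = 20


def make_pairs(cs: ChoiceSet, rng: np.random.Generator) -> pd.DataFrame:
    """Randomly labelled real/alternative pairs, one per stratum.

    Requires choice sets built with exactly one alternative (K = 1).
    Columns: ``y`` (1 iff location 1 is the real endpoint), ``dn`` (the
    recently-used difference n1 - n2), per-location road flags, the
    focal's previous road flag, the sleep-directedness difference and the
    time-of-day bin. Deterministic given the generator state.
    """
    if cs.n_candidates != 2:
        raise ValueError(
            f"paired analysis requires K=1 (2 candidates), got {cs.n_candidates}"
        )
    n = cs.n_strata
    # random assignment of the labels location 1 / location 2
    loc1_is_cand = rng.integers(0, 2, size=n)  # candidate index called location 1
    idx = np.arange(n)
    real = cs.chosen  # index of the real endpoint
    y = (loc1_is_cand == real).astype(int)
    loc2_is_cand = 1 - loc1_is_cand
    rec = cs.raw["recently_used"]
    road = cs.raw["road"]
    sdir = cs.raw["sleep_dir"]
    return pd.DataFrame(
        {
            "y": y,
            "dn": rec[idx, loc1_is_cand] - rec[idx, loc2_is_cand],
            "road1": road[idx, loc1_is_cand].astype(int),
            "road2": road[idx, loc2_is_cand].astype(int),
            "prev_road": cs.prev_road.astype(int),
            "sleep_diff": sdir[idx, loc1_is_cand] - sdir[idx, loc2_is_cand],
            "tod": cs.tod,
            "focal_id": cs.focal,
        }
    )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta quantiles."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid binomial counts k={k}, n={n}")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def curve(
    pairs: pd.DataFrame,
    condition: Optional[pd.Series] = None,
    dn_range: int = DEFAULT_DN_RANGE,
    min_bin_n: int = DEFAULT_MIN_BIN_N,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """P(location 1 real) per recently-used-difference bin with exact CIs.

    ``dn`` is binned at integer values with tails pooled at +-``dn_range``;
    bins with fewer than ``min_bin_n`` pairs are suppressed.
    """
    sel = pairs if condition is None else pairs[np.asarray(condition, dtype=bool)]
    if len(sel) == 0:
        warnings.warn("empty selection after filtering; returning empty curve")
        return pd.DataFrame(columns=["dn", "n", "k", "p", "lo", "hi"])
    dn = np.clip(sel["dn"].to_numpy(), -dn_range, dn_range).round().astype(int)
    rows = []
    for b in range(-dn_range, dn_range + 1):
        mask = dn == b
        n = int(mask.sum())
        if n == 0 or n < min_bin_n:
            continue
        k = int(sel["y"].to_numpy()[mask].sum())
        lo, hi = clopper_pearson(k, n, alpha)
        rows.append({"dn": b, "n": n, "k": k, "p": k / n, "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


ROAD_CASES = ("neither", "both", "loc1_only")


def road_conditioned_curves(
    pairs: pd.DataFrame, min_bin_n: int = DEFAULT_MIN_BIN_N
) -> dict:
    """Curves stratified by road context and the focal's starting surface.

    Returns ``{(started_on_road, case): curve}`` for case in
    {neither, both, loc1_only}. Pairs where only location 2 is on a road
    are folded into the loc1-only case by swapping the labels (dn and the
    outcome complemented), so the red-line case uses all available data.
    """
    p = pairs.copy()
    swap = (p["road2"] == 1) & (p["road1"] == 0)
    p.loc[swap, "y"] = 1 - p.loc[swap, "y"]
    p.loc[swap, "dn"] = -p.loc[swap, "dn"]
    p.loc[swap, "sleep_diff"] = -p.loc[swap, "sleep_diff"]
    p.loc[swap, ["road1", "road2"]] = [1, 0]
    out = {}
    for started in (1, 0):
        base = p["prev_road"] == started
        out[(started, "neither")] = curve(
            p, base & (p["road1"] == 0) & (p["road2"] == 0), min_bin_n=min_bin_n
        )
        out[(started, "both")] = curve(
            p, base & (p["road1"] == 1) & (p["road2"] == 1), min_bin_n=min_bin_n
        )
        out[(started, "loc1_only")] = curve(
            p, base & (p["road1"] == 1) & (p["road2"] == 0), min_bin_n=min_bin_n
        )
    return out


def sleepdir_conditioned_curves(
    pairs: pd.DataFrame,
    tod: int,
    n_bins: int = 4,
    min_bin_n: int = DEFAULT_MIN_BIN_N,
) -> dict:
    """Curves for one time-of-day bin, stratified by quartile (by default)
    of the sleep-directedness difference between the two locations."""
    sel = pairs[pairs["tod"] == tod]
    if len(sel) == 0:
        warnings.warn(f"no pairs in time-of-day bin {tod}")
        return {}
    edges = np.quantile(sel["sleep_diff"], np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    out = {}
    for b in range(n_bins):
        mask = (sel["sleep_diff"] > edges[b]) & (sel["sleep_diff"] <= edges[b + 1])
        label = (float(edges[b]), float(edges[b + 1]))
        out[label] = curve(sel, mask, min_bin_n=min_bin_n)
    return out


@dataclasses.dataclass
class CrossingEstimate:
    """Logistic P=0.5 crossing of a curve family, with bootstrap CI."""

    crossing: float
    ci: tuple[float, float]
    slope: float


def logistic_crossing(
    pairs: pd.DataFrame,
    condition: Optional[pd.Series] = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> CrossingEstimate:
    """Fit P(y=1 | dn) logistic and report where it crosses 0.5.

    The crossing (in units of the recently-used difference) quantifies how
    many additional recent troop-mate passages offset the conditioning
    bias; CI from a seeded nonparametric bootstrap.
    """
    import statsmodels.api as sm

    sel = pairs if condition is None else pairs[np.asarray(condition, dtype=bool)]
    dn = sel["dn"].to_numpy(dtype=float)
    y = sel["y"].to_numpy(dtype=int)

    def _cross(dn, y):
        X = sm.add_constant(dn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        b0, b1 = fit.params
        return -b0 / b1, b1

    c, slope = _cross(dn, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(dn), len(dn))
        try:
            boots.append(_cross(dn[idx], y[idx])[0])
        except Exception:  # degenerate resample
            continue
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return CrossingEstimate(crossing=float(c), ci=(float(lo), float(hi)), slope=float(slope))
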