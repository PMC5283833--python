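"""Choice-set container and design-matrix coding for step selection.

One *stratum* is one movement decision: the chosen endpoint plus K sampled
alternatives, each with its raw feature values. The conditional-logit
design matrix codes the raw features into model terms:

* road and animal-path enter with their interaction with whether the
  previous location was on a road/path (``road``, ``road_x_prev_road``,
  ``path``, ``path_x_prev_path``);
* sleep-site directedness enters as one term per time-of-day bin
  (morning / midday / evening);
* everything else enters directly.

Terms are grouped into *feature blocks* that enter or leave all-subsets
model inference together, so per-feature Akaike weights are well defined.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# raw per-candidate feature columns
RAW_FEATURES = (
    "env_density",
    "social_density",
    "sleep_dir",
    "road",
    "recently_used",
    "ever_used",
    "path",
    "visible",
    "slope",
)

# design-matrix terms, in the fixed order of _kernels.decision_features
TERMS = (
    "env_density",
    "social_density",
    "sleep_morning",
    "sleep_midday",
    "sleep_evening",
    "road",
    "road_x_prev_road",
    "recently_used",
    "ever_used",
    "path",
    "path_x_prev_path",
    "visible",
    "slope",
)

# feature blocks for multi-model inference (interaction terms travel with
# their main effect; the three sleep terms form one block)
BLOCKS = {
    "env_density": ("env_density",),
    "social_density": ("social_density",),
    "sleep_dir": ("sleep_morning", "sleep_midday", "sleep_evening"),
    "road": ("road", "road_x_prev_road"),
    "recently_used": ("recently_used",),
    "ever_used": ("ever_used",),
    "path": ("path", "path_x_prev_path"),
    "visible": ("visible",),
    "slope": ("slope",),
}
BLOCK_NAMES = tuple(BLOCKS)

HABITAT_BLOCKS = ("env_density", "sleep_dir", "road", "path", "slope", "ever_used")
SOCIAL_BLOCKS = ("social_density", "recently_used", "visible", "ever_used")

DEFAULT_TOD_BINS = (10.0, 16.0)  # morning < 10:00 <= midday < 16:00 <= evening
TOD_LABELS = ("morning", "midday", "evening")


def tod_of(hour: float, tod_bins=DEFAULT_TOD_BINS) -> int:
    """Time-of-day bin index (0 morning, 1 midday, 2 evening) of a clock hour."""
    h = hour % 24.0
    if h < tod_bins[0]:
        return 0
    if h < tod_bins[1]:
        return 1
    return 2


@dataclasses.dataclass
class ChoiceSet:
    """Array-backed set of movement-decision strata.

    Attributes
    ----------
    focal : (n,) object array of individual ids
    t : (n,) datetime64[s] decision timestamps
    p_start : (n, 2) step start points
    cand_xy : (n, m, 2) candidate endpoints (m = K + 1)
    chosen : (n,) index of the truly chosen candidate
    raw : dict of (n, m) arrays, one per RAW_FEATURES entry
    prev_road, prev_path : (n,) whether the start point was on a road/path
    tod : (n,) time-of-day bin index
    n_dropped : strata discarded during assembly (off-raster or missing)
    """

    focal: np.ndarray
    t: np.ndarray
    p_start: np.ndarray
    cand_xy: np.ndarray
    chosen: np.ndarray
    raw: dict
    prev_road: np.ndarray
    prev_path: np.ndarray
    tod: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n, m, _ = self.cand_xy.shape
        if self.chosen.shape != (n,):
            raise ValueError("chosen must have one entry per stratum")
        if np.any((self.chosen < 0) | (self.chosen >= m)):
            raise ValueError("chosen index out of candidate range")
        for k in RAW_FEATURES:
            if k not in self.raw or self.raw[k].shape != (n, m):
                raise ValueError(f"raw feature {k!r} missing or mis-shaped")

    @property
    def n_strata(self) -> int:
        return len(self.chosen)

    @property
    def n_candidates(self) -> int:
        return self.cand_xy.shape[1]

    def design_matrix(self, blocks: Optional[Sequence[str]] = None):
        """(X, term_names): X has shape (n, m, p).

        ``blocks`` selects feature blocks (default: all); term order follows
        TERMS restricted to the chosen blocks.
        """
        if blocks is None:
            blocks = BLOCK_NAMES
        unknown = set(blocks) - set(BLOCK_NAMES)
        if unknown:
            raise KeyError(f"unknown feature blocks: {sorted(unknown)}")
        terms = [t for t in TERMS if any(t in BLOCKS[b] for b in blocks)]
        n, m, _ = self.cand_xy.shape
        X = np.zeros((n, m, len(terms)))
        for j, term in enumerate(terms):
            X[:, :, j] = self._term_column(term)
        return X, terms

    def _term_column(self, term: str) -> np.ndarray:
        if term in ("sleep_morning", "sleep_midday", "sleep_evening"):
            bin_idx = ("sleep_morning", "sleep_midday", "sleep_evening").index(term)
            return self.raw["sleep_dir"] * (self.tod == bin_idx)[:, None]
        if term == "road_x_prev_road":
            return self.raw["road"] * self.prev_road[:, None]
        if term == "path_x_prev_path":
            return self.raw["path"] * self.prev_path[:, None]
        return self.raw[term]

    def subset(self, idx) -> "ChoiceSet":
        idx = np.asarray(idx)
        return ChoiceSet(
            focal=self.focal[idx],
            t=self.t[idx],
            p_start=self.p_start[idx],
            cand_xy=self.cand_xy[idx],
            chosen=self.chosen[idx],
            raw={k: v[idx] for k, v in self.raw.items()},
            prev_road=self.prev_road[idx],
            prev_path=self.prev_path[idx],
            tod=self.tod[idx],
            n_dropped=0,
        )

    def for_focal(self, focal_id) -> "ChoiceSet":
        return self.subset(np.flatnonzero(self.focal == focal_id))

    @property
    def focal_ids(self):
        return pd.unique(self.focal)

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (stratum, candidate)."""
        n, m, _ = self.cand_xy.shape
        s = np.repeat(np.arange(n), m)
        df = pd.DataFrame(
            {
                "stratum_id": s,
                "candidate_id": np.tile(np.arange(m), n),
                "chosen": (np.tile(np.arange(m), n) == np.repeat(self.chosen, m)).astype(int),
                "focal_id": np.repeat(self.focal, m),
                "t": np.repeat(self.t, m),
                "x_start": np.repeat(self.p_start[:, 0], m),
                "y_start": np.repeat(self.p_start[:, 1], m),
                "x": self.cand_xy[:, :, 0].ravel(),
                "y": self.cand_xy[:, :, 1].ravel(),
                "prev_road": np.repeat(self.prev_road, m),
                "prev_path": np.repeat(self.prev_path, m),
                "tod": np.repeat(self.tod, m),
            }
        )
        for k in RAW_FEATURES:
            df[k] = self.raw[k].ravel()
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceSet":
        df = df.sort_values(["stratum_id", "candidate_id"]).reset_index(drop=True)
        m = int(df["candidate_id"].max()) + 1
        n = df["stratum_id"].nunique()
        if len(df) != n * m:
            raise ValueError("ragged choice-set table")
        first = df.iloc[::m]
        chosen = (
            df[df["chosen"] == 1].sort_values("stratum_id")["candidate_id"].to_numpy()
        )
        return cls(
            focal=first["focal_id"].to_numpy(),
            t=pd.to_datetime(first["t"]).to_numpy().astype("datetime64[s]"),
            p_start=first[["x_start", "y_start"]].to_numpy(),
            cand_xy=df[["x", "y"]].to_numpy().reshape(n, m, 2),
            chosen=chosen,
            raw={k: df[k].to_numpy().reshape(n, m) for k in RAW_FEATURES},
            prev_road=first["prev_road"].to_numpy().astype(float),
            prev_path=first["prev_path"].to_numpy().astype(float),
            tod=first["tod"].to_numpy().astype(int),
        )

    @classmethod
    def read_csv(cls, path) -> "ChoiceSet":
        return cls.from_frame(pd.read_csv(path))


def concat_choice_sets(sets: Sequence[ChoiceSet]) -> ChoiceSet:
    """Stack strata from several choice sets (equal candidate counts)."""
    ms = {cs.n_candidates for cs in sets}
    if len(ms) != 1:
        raise ValueError(f"candidate counts differ: {ms}")
    return ChoiceSet(
        focal=np.concatenate([cs.focal for cs in sets]),
        t=np.concatenate([cs.t for cs in sets]),
        p_start=np.concatenate([cs.p_start for cs in sets]),
        cand_xy=np.concatenate([cs.cand_xy for cs in sets]),
        chosen=np.concatenate([cs.chosen for cs in sets]),
        raw={
            k: np.concatenate([cs.raw[k] for cs in sets]) for k in RAW_FEATURES
        },
        prev_road=np.concatenate([cs.prev_road for cs in sets]),
        prev_path=np.concatenate([cs.prev_path for cs in sets]),
        tod=np.concatenate([cs.tod for cs in sets]),
        n_dropped=sum(cs.n_dropped for cs in sets),
    )
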