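"""End-to-end run configuration and orchestration.

A single YAML-serializable :class:`RunConfig` drives the full pipeline:
simulate (or load) -> preprocess -> discretize -> choice sets -> fits ->
scale profiles -> multi-model inference -> cross-validation -> paired
analysis -> group metrics -> context models. Every stage writes CSV
artifacts into the output directory and the run manifest records a SHA-256
hash per artifact plus the seeds used, so identical configs reproduce
identical outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import direct_prob, group, ssf, synthetic, trajectories
from .choiceset import DEFAULT_TOD_BINS
from .landscape import Landscape

logger = logging.getLogger(__name__)


class ScalesConfig(BaseModel):
    env_density_radius_m: float = 2.5
    social_density_radius_m: float = 4.25
    recently_used_window_s: float = 270.0
    occupancy_radius_m: float = 1.25
    los_density_threshold: float = 0.5

    @field_validator(
        "env_density_radius_m",
        "social_density_radius_m",
        "recently_used_window_s",
        "occupancy_radius_m",
    )
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v


class SimulateConfig(BaseModel):
    landscape: dict = Field(default_factory=dict)
    agents: dict = Field(default_factory=dict)


class StepsConfig(BaseModel):
    step_length_m: float = 5.0
    K: int = 10
    speed_max_ms: float = 8.0
    max_gap_s: int = 1

    @field_validator("step_length_m")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @field_validator("K")
    @classmethod
    def _k(cls, v):
        if v < 1:
            raise ValueError(f"K must be >= 1, got {v}")
        return v


class RunConfig(BaseModel):
    """Validated end-to-end run configuration."""

    seed: int = 0
    out_dir: str = "troopstep_run"
    trajectories_csv: Optional[str] = None  # if None, simulate
    landscape_dir: Optional[str] = None
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    scales: ScalesConfig = Field(default_factory=ScalesConfig)
    steps: StepsConfig = Field(default_factory=StepsConfig)
    tod_bins: tuple[float, float] = DEFAULT_TOD_BINS
    crossval_folds: int = 2
    scale_grids: dict = Field(
        default_factory=lambda: {
            "recently_used": [60.0, 270.0, 900.0],
            "env_density": [1.0, 2.5, 5.0, 10.0],
        }
    )
    run_scale_inference: bool = True
    run_mmi: bool = True
    run_directprob: bool = True
    run_group: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(self.model_dump_json())))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    manifest: dict = {"seed": config.seed, "stages": {}, "stage_seeds": {}}

    def record(stage: str, *paths: Path):
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}

    # --- stage: landscape + trajectories ---------------------------------
    if config.trajectories_csv is None:
        ls_seed = int(seeds[0].generate_state(1)[0] % 2**31)
        ag_seed = int(seeds[1].generate_state(1)[0] % 2**31)
        lcfg = synthetic.LandscapeConfig(**{**config.simulate.landscape, "seed": ls_seed})
        acfg = synthetic.AgentConfig(
            **{
                **config.simulate.agents,
                "seed": ag_seed,
                "tod_bins": tuple(config.tod_bins),
            }
        )
        manifest["stage_seeds"] = {"landscape": ls_seed, "agents": ag_seed}
        ls = synthetic.gen_landscape(lcfg)
        traj, choice_log = synthetic.simulate_troop(ls, acfg)
        ls.write_dir(out / "landscape")
        traj.to_csv(out / "trajectories.csv")
        choice_log.to_csv(out / "choice_log.csv")
        record(
            "simulate",
            out / "trajectories.csv",
            out / "choice_log.csv",
            *(out / "landscape").glob("*"),
        )
    else:
        if config.landscape_dir is None:
            raise ValueError("landscape_dir is required with trajectories_csv input")
        ls = Landscape.read_dir(config.landscape_dir)
        traj = trajectories.read_trajectories(config.trajectories_csv)
        choice_log = None

    # --- stage: preprocess -------------------------------------------------
    traj = trajectories.fill_gaps(traj, max_gap_s=config.steps.max_gap_s)
    traj = trajectories.filter_outliers(traj, speed_max_ms=config.steps.speed_max_ms)

    # --- stage: steps + choice sets ---------------------------------------
    all_steps = []
    for fid in traj.ids:
        all_steps.extend(
            trajectories.discretize_steps(traj, fid, config.steps.step_length_m)
        )
    trajectories.steps_to_frame(all_steps).to_csv(out / "steps.csv", index=False)
    record("steps", out / "steps.csv")
    dists = trajectories.empirical_dists(all_steps)
    ctx = ssf.FeatureContext(
        ls, traj, scales=config.scales.model_dump(), tod_bins=tuple(config.tod_bins)
    )
    rng_cs = np.random.default_rng(seeds[2])
    cs = ssf.build_choice_sets(all_steps, dists, config.steps.K, ctx, rng_cs)
    cs.to_csv(out / "choice_sets.csv")
    record("choice_sets", out / "choice_sets.csv")

    # --- stage: fits -------------------------------------------------------
    fits = []
    for fid in cs.focal_ids:
        res = ssf.fit_clogit(cs.for_focal(fid))
        row = res.params.rename(lambda t: f"coef_{t}").to_dict()
        row.update(res.bse.rename(lambda t: f"se_{t}").to_dict())
        row.update(
            focal_id=fid, llf=res.llf, aic=res.aic, converged=res.converged,
            n_strata=res.model.n_strata,
        )
        fits.append(row)
    pd.DataFrame(fits).to_csv(out / "fits.csv", index=False)
    record("fit", out / "fits.csv")

    # --- stage: scale profiles --------------------------------------------
    if config.run_scale_inference:
        rows = []
        for feature, grid in config.scale_grids.items():
            prof = ssf.infer_scale(cs, feature, grid, ctx)
            for s, ll in zip(prof.grid, prof.loglik):
                rows.append(
                    {"feature": feature, "scale": s, "loglik": ll, "best": prof.best_scale}
                )
        pd.DataFrame(rows).to_csv(out / "scale_profiles.csv", index=False)
        record("scales", out / "scale_profiles.csv")

    # --- stage: multi-model inference --------------------------------------
    if config.run_mmi:
        fw = ssf.all_subsets_aic(cs)
        fw.per_individual.to_csv(out / "feature_weights.csv")
        record("mmi", out / "feature_weights.csv")

    # --- stage: cross-validated predictive comparison ----------------------
    losses = ssf.oos_log_loss(cs, n_folds=config.crossval_folds)
    pd.Series(losses, name="neg_log_loss").to_csv(out / "crossval.csv")
    record("crossval", out / "crossval.csv")

    # --- stage: direct paired-choice analysis ------------------------------
    if config.run_directprob:
        rng_dp = np.random.default_rng(seeds[3])
        cs1 = ssf.build_choice_sets(all_steps, dists, 1, ctx, rng_dp)
        pairs = direct_prob.make_pairs(cs1, rng_dp)
        pairs.to_csv(out / "pairs.csv", index=False)
        direct_prob.curve(pairs).to_csv(out / "curve_overall.csv", index=False)
        record("directprob", out / "pairs.csv", out / "curve_overall.csv")

    # --- stage: group structure --------------------------------------------
    if config.run_group:
        states = group.group_metrics(traj)
        labels = group.context_labels(traj, ls, tod_bins=tuple(config.tod_bins))
        states.to_csv(out / "group_states.csv")
        labels.to_csv(out / "context_labels.csv")
        cm = group.context_linear_models(states, labels)
        cm.to_csv(out / "context_models.csv")
        record(
            "group",
            out / "group_states.csv",
            out / "context_labels.csv",
            out / "context_models.csv",
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
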