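"""Conditional-logit fitting, scale inference, multi-model inference,
cross-validated prediction and preference landscapes."""

import numpy as np
import pandas as pd
import pytest

from troopstep import (
    FeatureContext,
    StepSelectionModel,
    all_subsets_aic,
    build_choice_sets,
    clogit_loglik,
    discretize_steps,
    empirical_dists,
    fit_clogit,
    infer_scale,
    oos_log_loss,
    preference_landscape,
)
from troopstep.choiceset import BLOCK_NAMES, ChoiceSet, RAW_FEATURES, TERMS
from troopstep.synthetic import FORAGING_BETA


def toy_choice_set(X, chosen):
    """Wrap a bare design matrix in a single-feature-block ChoiceSet-like
    model (used where the ChoiceSet plumbing is irrelevant)."""
    return StepSelectionModel(X, chosen, [f"f{j}" for j in range(X.shape[2])])


class TestLikelihood:
    def test_null_loglik_exact(self, foraging_sim):
        _, _, log = foraging_sim
        beta0 = np.zeros(len(TERMS))
        ll = clogit_loglik(beta0, log)
        assert ll == pytest.approx(-log.n_strata * np.log(log.n_candidates), rel=1e-12)

    def test_two_stratum_grid_oracle(self):
        # 2 strata, 1 feature: MLE against a dense grid search
        # opposing preferences across strata give an interior maximum
        X = np.zeros((2, 2, 1))
        X[0, :, 0] = [1.0, 0.0]
        X[1, :, 0] = [0.3, 1.0]
        chosen = np.array([0, 0])
        model = toy_choice_set(X, chosen)
        res = model.fit()
        grid = np.arange(-10, 10, 1e-4)
        u0 = X[0, :, 0][None, :] * grid[:, None]
        u1 = X[1, :, 0][None, :] * grid[:, None]
        ll = (
            u0[:, 0] - np.log(np.exp(u0).sum(1))
            + u1[:, 0] - np.log(np.exp(u1).sum(1))
        )
        best = grid[np.argmax(ll)]
        assert res.params.iloc[0] == pytest.approx(best, abs=1e-3)
        assert res.llf >= ll.max() - 1e-10

    def test_matches_statsmodels_conditional_logit(self, foraging_sim):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        _, _, log = foraging_sim
        sub = log.subset(np.arange(300))
        blocks = ("env_density", "recently_used", "road")
        X, terms = sub.design_matrix(blocks)
        res = fit_clogit(sub, feature_subset=blocks)
        n, m, p = X.shape
        y = np.zeros((n, m))
        y[np.arange(n), sub.chosen] = 1
        groups = np.repeat(np.arange(n), m)
        sm_res = ConditionalLogit(y.ravel(), X.reshape(n * m, p), groups=groups).fit(
            method="newton", disp=0
        )
        assert np.allclose(res.params.to_numpy(), sm_res.params, atol=1e-5)
        assert np.allclose(res.bse.to_numpy(), sm_res.bse, atol=1e-4)
        assert res.llf == pytest.approx(sm_res.llf, abs=1e-6)

    def test_location_invariance(self, foraging_sim):
        # adding a constant to a feature within every stratum changes nothing
        _, _, log = foraging_sim
        sub = log.subset(np.arange(400))
        X, terms = sub.design_matrix(("env_density", "recently_used"))
        res1 = toy_choice_set(X, sub.chosen).fit()
        X2 = X.copy()
        X2[:, :, 0] += 7.3
        res2 = toy_choice_set(X2, sub.chosen).fit()
        assert np.allclose(res1.params, res2.params, atol=1e-7)
        assert res1.llf == pytest.approx(res2.llf, abs=1e-8)

    def test_loglik_at_mle_beats_null(self, foraging_sim):
        _, _, log = foraging_sim
        res = fit_clogit(log)
        assert res.converged
        assert res.llf >= res.llnull

    def test_recovery_on_choice_log(self, foraging_sim):
        # a morning-only run leaves the midday/evening sleep terms with
        # all-zero columns; recovery is asserted on the identified terms
        _, _, log = foraging_sim
        res = fit_clogit(log)
        truth = np.array([FORAGING_BETA.get(t, 0.0) for t in res.params.index])
        identified = res.bse.to_numpy() > 1e-6
        assert identified.sum() >= 11
        z = (res.params.to_numpy()[identified] - truth[identified]) / res.bse.to_numpy()[identified]
        assert np.all(np.abs(z) < 4.0)

    def test_aic_identity_and_summary(self, foraging_sim):
        _, _, log = foraging_sim
        res = fit_clogit(log, feature_subset=("recently_used", "road"))
        assert res.aic == pytest.approx(2 * res.df_model - 2 * res.llf)
        text = res.summary()
        assert "recently_used" in text and "Log-likelihood" in text

    def test_separation_flagged(self):
        # a feature that perfectly predicts the choice diverges
        rng = np.random.default_rng(0)
        n = 60
        X = rng.normal(size=(n, 2, 1))
        chosen = np.argmax(X[:, :, 0], axis=1)
        res = toy_choice_set(X, chosen).fit(maxiter=200)
        assert res.separation
        ridge = StepSelectionModel(X, chosen, ["f0"], ridge=1.0).fit()
        assert np.isfinite(ridge.params.iloc[0])


class TestStandardize:
    def test_standardized_fit_matches_raw_scale(self, foraging_sim):
        _, _, log = foraging_sim
        sub = log.subset(np.arange(500))
        blocks = ("env_density", "recently_used")
        raw = fit_clogit(sub, feature_subset=blocks)
        std = fit_clogit(sub, feature_subset=blocks, standardize=True)
        # reported on the raw scale either way
        assert np.allclose(raw.params, std.params, atol=1e-6)
        assert np.allclose(raw.bse, std.bse, atol=1e-6)


class TestBuildChoiceSets:
    def test_counts_and_consistency(self, foraging_sim):
        ls, traj, log = foraging_sim
        steps = discretize_steps(traj, traj.ids[0], 5.0)[:50]
        dists = empirical_dists(steps)
        ctx = FeatureContext(ls, traj)
        cs = build_choice_sets(steps, dists, 1, ctx, np.random.default_rng(0))
        assert cs.n_candidates == 2
        assert cs.n_strata + cs.n_dropped == 50
        assert np.all(cs.chosen == 0)

    def test_features_match_per_feature_oracles(self, foraging_sim):
        from troopstep import habitat, social
        from troopstep.social import OccupancyIndex

        ls, traj, _ = foraging_sim
        steps = discretize_steps(traj, traj.ids[2], 5.0)[10:20]
        dists = empirical_dists(steps)
        ctx = FeatureContext(ls, traj)
        cs = build_choice_sets(steps, dists, 2, ctx, np.random.default_rng(1))
        idx = OccupancyIndex(traj, 1.25)
        focal_idx = traj.index_of(traj.ids[2])
        for i in range(cs.n_strata):
            i_t = traj.t_index(cs.t[i])
            pos = traj.positions_at(i_t)
            for j in range(cs.n_candidates):
                c = cs.cand_xy[i, j]
                assert cs.raw["env_density"][i, j] == pytest.approx(
                    habitat.env_density(ls, c, 2.5)
                )
                assert cs.raw["road"][i, j] == habitat.on_road(ls, c)
                assert cs.raw["slope"][i, j] == pytest.approx(
                    habitat.slope(ls, cs.p_start[i], c), abs=1e-9
                )
                assert cs.raw["sleep_dir"][i, j] == pytest.approx(
                    habitat.sleep_dir(cs.p_start[i], c, ls.sleep_site), abs=1e-9
                )
                assert cs.raw["social_density"][i, j] == pytest.approx(
                    social.social_density(pos, focal_idx, c)
                )
                assert cs.raw["recently_used"][i, j] == idx.recent_count(
                    [c], i_t, 270, 1.25, focal_idx
                )[0]

    def test_empty_steps_error(self, foraging_sim):
        ls, traj, _ = foraging_sim
        ctx = FeatureContext(ls, traj)
        from troopstep.trajectories import EmpiricalStepDists, InsufficientDataError

        d = EmpiricalStepDists(np.array([5.0]), np.array([0.0]))
        with pytest.raises(InsufficientDataError):
            build_choice_sets([], d, 1, ctx, np.random.default_rng(0))


class TestScaleInference:
    def test_recover_both_scales(self, foraging_sim):
        ls, traj, log = foraging_sim
        ctx = FeatureContext(ls, traj)
        pw = infer_scale(log, "recently_used", [60.0, 270.0, 900.0], ctx)
        assert pw.best_scale == 270.0
        pe = infer_scale(log, "env_density", [1.0, 2.5, 5.0, 10.0], ctx)
        assert pe.best_scale == 2.5
        assert np.nanargmax(pw.loglik) == list(pw.grid).index(pw.best_scale)

    def test_null_feature_flat_profile(self):
        # a feature with no true effect yields a near-flat profile
        from troopstep import gen_landscape, simulate_troop
        from troopstep.synthetic import AgentConfig, LandscapeConfig

        ls = gen_landscape(LandscapeConfig(extent_m=(300.0, 300.0), seed=61))
        traj, log = simulate_troop(
            ls,
            AgentConfig(
                n_agents=8,
                n_steps=250,
                beta_true={"road": 0.8, "sleep_morning": 0.3},  # env has no effect
                seed=62,
            ),
        )
        ctx = FeatureContext(ls, traj)
        prof = infer_scale(log, "env_density", [1.0, 2.5, 5.0, 10.0], ctx)
        assert np.nanmax(prof.loglik) - np.nanmin(prof.loglik) < 5.0

    def test_empty_grid_error(self, foraging_sim):
        ls, traj, log = foraging_sim
        ctx = FeatureContext(ls, traj)
        with pytest.raises(ValueError):
            infer_scale(log, "env_density", [], ctx)


class TestMultiModelInference:
    def test_feature_weights_bounded_and_complete(self, foraging_sim):
        _, _, log = foraging_sim
        few = log.subset(np.arange(600))
        fw = all_subsets_aic(few, features=("recently_used", "road", "path", "slope"))
        w = fw.per_individual
        assert ((w >= 0) & (w <= 1)).all().all()
        assert set(w.columns) == {"recently_used", "road", "path", "slope"}
        assert set(fw.medians.index) == set(w.columns)

    def test_dominant_feature_ranks_first(self, foraging_sim):
        _, _, log = foraging_sim
        fw = all_subsets_aic(log, features=("recently_used", "path", "slope", "visible"))
        med = fw.medians
        assert med["recently_used"] >= med.drop("recently_used").max() - 1e-9
        assert med["path"] <= med["recently_used"] - 0.05

    def test_duplicated_feature_completes_flagged(self, foraging_sim):
        _, _, log = foraging_sim
        sub = log.subset(np.arange(200))
        dup = ChoiceSet(
            focal=sub.focal,
            t=sub.t,
            p_start=sub.p_start,
            cand_xy=sub.cand_xy,
            chosen=sub.chosen,
            raw={**sub.raw, "path": sub.raw["road"].copy()},  # path := duplicate of road
            prev_road=sub.prev_road,
            prev_path=sub.prev_road,
            tod=sub.tod,
        )
        fw = all_subsets_aic(dup, features=("road", "path"))
        w = fw.per_individual
        assert np.isfinite(w.to_numpy()).all()
        assert ((w >= 0) & (w <= 1)).all().all()

    def test_equal_aic_toy_weights(self):
        # hand-computed: two single-feature models with identical AIC share
        # the weight mass symmetrically
        aics = np.array([100.0, 100.0])
        d = aics - aics.min()
        w = np.exp(-d / 2)
        w /= w.sum()
        assert np.allclose(w, [0.5, 0.5])


class TestOOSLogLoss:
    def test_null_exact(self, foraging_sim):
        _, _, log = foraging_sim
        out = oos_log_loss(log.subset(np.arange(200)), n_folds=2, classes=("null",))
        assert out["null"] == pytest.approx(np.log(log.n_candidates), rel=1e-12)

    def test_full_beats_null_with_signal(self, foraging_sim):
        _, _, log = foraging_sim
        out = oos_log_loss(log, n_folds=3)
        assert out["full"] < out["null"]
        assert out["habitat_only"] < out["null"]
        assert out["social_only"] < out["null"]

    def test_permuted_labels_no_information(self, foraging_sim):
        _, _, log = foraging_sim
        rng = np.random.default_rng(0)
        sub = log.subset(np.arange(1500))
        shuffled = ChoiceSet(
            focal=sub.focal,
            t=sub.t,
            p_start=sub.p_start,
            cand_xy=sub.cand_xy,
            chosen=rng.integers(0, sub.n_candidates, sub.n_strata),
            raw=sub.raw,
            prev_road=sub.prev_road,
            prev_path=sub.prev_path,
            tod=sub.tod,
        )
        out = oos_log_loss(shuffled, n_folds=3, classes=("null", "full"))
        assert out["full"] >= out["null"] - 0.05

    def test_bad_folds(self, foraging_sim):
        _, _, log = foraging_sim
        with pytest.raises(ValueError):
            oos_log_loss(log, n_folds=1)


class TestPreferenceLandscape:
    def test_log_linearity_and_degenerate_cases(self, foraging_sim):
        ls, traj, log = foraging_sim
        res = fit_clogit(log)
        ctx = FeatureContext(ls, traj)
        i_t = 600
        fid = traj.ids[0]
        p = traj.xy[traj.index_of(fid), i_t]
        panels = preference_landscape(
            res, ctx, traj.times[i_t], fid, p,
            extent=(p[0] - 15, p[0] + 15, p[1] - 15, p[1] + 15),
        )
        prod = np.ones_like(panels["all"])
        for b in BLOCK_NAMES:
            prod = prod * panels[b]
        assert np.max(np.abs(prod - panels["all"])) < 1e-9 * max(1.0, panels["all"].max())

        # all-zero coefficients -> constant combined panel
        zero = res.params * 0.0
        res0 = type(res)(
            model=res.model, params=zero, cov_params_arr=res.cov_params_arr,
            llf=res.llf, llnull=res.llnull, converged=True, separation=False,
            collinear=False, niter=1,
        )
        panels0 = preference_landscape(
            res0, ctx, traj.times[i_t], fid, p,
            extent=(p[0] - 10, p[0] + 10, p[1] - 10, p[1] + 10),
        )
        assert np.allclose(panels0["all"], panels0["all"].ravel()[0])

    def test_single_road_feature_max_on_road(self, foraging_sim):
        ls, traj, log = foraging_sim
        res = fit_clogit(log, feature_subset=("road",))
        assert res.params["road"] > 0
        ctx = FeatureContext(ls, traj)
        i_t = 400
        fid = traj.ids[1]
        p = traj.xy[traj.index_of(fid), i_t]
        panels = preference_landscape(
            res, ctx, traj.times[i_t], fid, p,
            extent=(p[0] - 30, p[0] + 30, p[1] - 30, p[1] + 30), normalize=True,
        )
        road_panel = panels["road"]
        xs = panels["_meta"]["xs"]
        ys = panels["_meta"]["ys"]
        gx, gy = np.meshgrid(xs, ys)
        rr, cc = ls.world_to_cell(gx.ravel(), gy.ravel())
        on_road = ls.roads[rr, cc].reshape(road_panel.shape) > 0
        if on_road.any() and (~on_road).any():
            assert road_panel[on_road].min() > road_panel[~on_road].max() - 1e-9
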