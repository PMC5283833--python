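"""Six-metric group structure, context labels and context models."""

import numpy as np
import pandas as pd
import pytest

from troopstep import (
    context_labels,
    context_linear_models,
    group_metrics,
    hist2d_context_diff,
)
from troopstep.group import METRICS

from conftest import make_landscape, make_trajectories


def formation(offsets):
    """Tracks for individuals marching east at 1 m/s in a fixed formation."""
    base = np.column_stack((np.arange(800, dtype=float), np.zeros(800)))
    return {
        f"i{j}": base + np.asarray(off, dtype=float) for j, off in enumerate(offsets)
    }


class TestAnalyticFixtures:
    def test_square_formation_east(self):
        ts = make_trajectories(
            formation([(0, 0), (0, 4), (4, 0), (4, 4)]), t0="2012-08-01 08:00:00"
        )
        g = group_metrics(ts)
        row = g.iloc[2]
        assert row["speed"] == pytest.approx(60.0)
        assert row["polarization"] == pytest.approx(1.0)
        assert row["elongation"] == pytest.approx(0.0, abs=1e-12)  # isotropic square
        assert row["directedness"] == pytest.approx(1.0)

    def test_opposite_headings_zero_polarization(self):
        east = np.column_stack((np.arange(200, dtype=float), np.zeros(200)))
        west = np.column_stack((200 - np.arange(200, dtype=float), np.full(200, 5.0)))
        north = np.column_stack((np.zeros(200), np.arange(200, dtype=float)))
        south = np.column_stack((np.full(200, 5.0), 200 - np.arange(200, dtype=float)))
        ts = make_trajectories({"a": east, "b": west, "c": north, "d": south})
        g = group_metrics(ts)
        assert g.iloc[1]["polarization"] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_along_travel(self):
        ts = make_trajectories(formation([(0, 0), (-5, 0), (-10, 0), (-15, 0)]))
        g = group_metrics(ts)
        row = g.iloc[1]
        assert row["elongation"] == pytest.approx(1.0)
        assert row["tilt"] == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_line_tilt_90(self):
        ts = make_trajectories(formation([(0, 0), (0, 5), (0, 10), (0, 15)]))
        g = group_metrics(ts)
        assert g.iloc[1]["tilt"] == pytest.approx(90.0)

    def test_spread_two_individuals_insufficient(self):
        # spread needs >= 3 contributors: verify the 3-individual value
        ts = make_trajectories(formation([(0, 0), (0, 10), (0, 5)]))
        g = group_metrics(ts)
        assert g.iloc[0]["n"] == 3
        assert g.iloc[0]["spread"] == pytest.approx((5 + 5 + 0) / 3)

    def test_closed_loop_zero_directedness(self):
        # centroid traverses a circle returning to start within the window
        t = np.arange(700, dtype=float)
        theta = 2 * np.pi * t / 600.0
        circ = np.column_stack((50 * np.cos(theta), 50 * np.sin(theta)))
        ts = make_trajectories({f"i{j}": circ + [j, 0.0] for j in range(3)})
        g = group_metrics(ts)
        assert g.iloc[0]["directedness"] == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_three_missing(self):
        ts = make_trajectories(formation([(0, 0), (5, 0)]))
        g = group_metrics(ts)
        assert np.isnan(g.iloc[0][list(METRICS)].astype(float)).all()


class TestBruteForceOracle:
    def test_random_configuration_matches(self):
        rng = np.random.default_rng(0)
        n_ind, n_t = 8, 1500
        tracks = {
            f"i{j}": rng.uniform(0, 50, 2) + rng.normal(0, 0.8, (n_t, 2)).cumsum(axis=0)
            for j in range(n_ind)
        }
        ts = make_trajectories(tracks)
        g = group_metrics(ts)
        xy = ts.xy
        k = 5  # check an interior minute
        t0 = 60 * k
        p0 = xy[:, t0, :]
        p1 = xy[:, t0 + 60, :]
        c0, c1 = p0.mean(0), p1.mean(0)
        assert g.iloc[k]["speed"] == pytest.approx(np.linalg.norm(c1 - c0), abs=1e-9)
        d = p1 - p0
        dn = np.linalg.norm(d, axis=1)
        unit = d[dn >= 1.0] / dn[dn >= 1.0, None]
        assert g.iloc[k]["polarization"] == pytest.approx(
            np.linalg.norm(unit.mean(0)), abs=1e-9
        )
        assert g.iloc[k]["spread"] == pytest.approx(
            np.linalg.norm(p0 - c0, axis=1).mean(), abs=1e-9
        )
        cov = np.cov(p0.T, bias=True)
        ev = np.sort(np.linalg.eigvalsh(cov))
        assert g.iloc[k]["elongation"] == pytest.approx(
            (ev[1] - ev[0]) / (ev[1] + ev[0]), abs=1e-9
        )
        evals, evecs = np.linalg.eigh(cov)
        axis = evecs[:, -1]
        disp = c1 - c0
        ang = np.degrees(
            np.arccos(abs(axis @ disp) / np.linalg.norm(disp))
        )
        assert g.iloc[k]["tilt"] == pytest.approx(ang, abs=1e-9)
        cents = np.array(
            [xy[:, 60 * j, :].mean(0) for j in range(k, k + 11)]
        )
        path = np.linalg.norm(np.diff(cents, axis=0), axis=1).sum()
        assert g.iloc[k]["directedness"] == pytest.approx(
            np.linalg.norm(cents[-1] - cents[0]) / path, abs=1e-9
        )

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        tracks = {
            f"i{j}": rng.uniform(0, 30, 2) + rng.normal(0, 1.0, (400, 2)).cumsum(axis=0)
            for j in range(5)
        }
        ts = make_trajectories(tracks)
        g1 = group_metrics(ts)
        theta = 0.73
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        tracks2 = {k: v @ R.T + np.array([1000.0, -500.0]) for k, v in tracks.items()}
        g2 = group_metrics(make_trajectories(tracks2))
        for m in METRICS:
            a, b = g1[m].to_numpy(), g2[m].to_numpy()
            ok = ~np.isnan(a)
            assert np.allclose(a[ok], b[ok], atol=1e-8)


class TestContextLabels:
    def test_bare_ground_and_road_presence(self):
        roads = np.zeros((60, 60))
        roads[30, :] = 1.0
        ls = make_landscape(n=60, roads=roads, sleep=(30.0, 30.0))
        on_road = formation([(20, 28), (22, 30), (24, 32)])  # hull crosses the road
        ts = make_trajectories({k: v[:130] for k, v in on_road.items()})
        labels = context_labels(ts, ls)
        assert labels.iloc[0]["env_density"] == 0.0
        assert labels.iloc[0]["road_present"] == 1.0

    def test_half_vegetated_hull_fraction(self):
        veg = np.zeros((60, 60))
        veg[:, 30:] = 1.0
        ls = make_landscape(n=60, veg=veg, sleep=(30.0, 30.0))
        pts = [(26, 26), (34, 26), (26, 34), (34, 34)]
        tracks = {f"i{j}": np.tile(p, (130, 1)).astype(float) for j, p in enumerate(pts)}
        # stationary: hull is the buffered square [26,34]^2 centered on x=30
        labels = context_labels(make_trajectories(tracks), ls)
        assert labels.iloc[0]["env_density"] == pytest.approx(0.5, abs=0.06)

    def test_tertiles_balanced(self):
        rng = np.random.default_rng(2)
        ls = make_landscape(n=80, veg=(rng.random((80, 80)) < 0.4).astype(float),
                            sleep=(40.0, 40.0))
        tracks = {
            f"i{j}": rng.uniform(10, 70, 2) + rng.normal(0, 0.5, (3700, 2)).cumsum(axis=0).clip(-30, 30)
            for j in range(4)
        }
        labels = context_labels(make_trajectories(tracks), ls)
        counts = labels["env_class"].value_counts()
        assert counts.max() - counts.min() <= 1


class TestHistDiff:
    def _states(self, rng, n=800, road_speed_boost=0.0):
        road = rng.integers(0, 2, n).astype(float)
        states = pd.DataFrame(
            {
                "speed": rng.gamma(4, 8, n) + road_speed_boost * road,
                "polarization": rng.beta(2, 2, n),
                "spread": rng.gamma(5, 2, n),
                "directedness": rng.beta(2, 2, n),
                "elongation": rng.beta(2, 3, n),
                "tilt": rng.uniform(0, 90, n),
                "n": 10,
            },
            index=pd.date_range("2012-08-01 06:00", periods=n, freq="1min"),
        )
        labels = pd.DataFrame(
            {
                "env_density": rng.beta(2, 4, n),
                "path_density": rng.beta(1, 8, n),
                "road_present": road,
                "time_of_day": rng.integers(0, 3, n),
            },
            index=states.index,
        )
        return states, labels

    def test_all_data_context_identically_zero(self):
        states, labels = self._states(np.random.default_rng(3))
        out = hist2d_context_diff(states, ("speed", "polarization"), np.ones(len(states), bool))
        assert np.allclose(out["diff"], 0.0, atol=1e-15)

    def test_diff_sums_to_zero(self):
        states, labels = self._states(np.random.default_rng(4))
        out = hist2d_context_diff(
            states, ("spread", "directedness"), labels["road_present"] == 1
        )
        assert abs(out["diff"].sum()) < 1e-12

    def test_road_speed_shift_direction(self):
        states, labels = self._states(np.random.default_rng(5), road_speed_boost=20.0)
        out = hist2d_context_diff(
            states, ("speed", "polarization"), labels["road_present"] == 1
        )
        edges_x = out["edges"][0]
        mids = (edges_x[:-1] + edges_x[1:]) / 2
        marg = out["diff"].sum(axis=1)
        # mass moves toward high speed in the on-road context
        assert (marg * mids).sum() > 0

    def test_empty_context_error(self):
        states, labels = self._states(np.random.default_rng(6))
        with pytest.raises(ValueError):
            hist2d_context_diff(
                states, ("speed", "polarization"), np.zeros(len(states), bool)
            )


class TestContextLinearModels:
    def _planted(self, rng, n=600, effect="road_present", amp=15.0):
        states = pd.DataFrame(
            index=pd.date_range("2012-08-01 06:00", periods=n, freq="1min"),
            columns=list(METRICS) + ["n"],
            dtype=float,
        )
        labels = pd.DataFrame(
            {
                "env_density": rng.beta(2, 4, n),
                "path_density": rng.beta(1, 8, n),
                "road_present": rng.integers(0, 2, n).astype(float),
                "time_of_day": rng.integers(0, 3, n),
            },
            index=states.index,
        )
        for m in METRICS:
            states[m] = rng.normal(10, 3, n)
        states["speed"] = 30 + amp * labels[effect] + rng.normal(0, 3, n)
        states["n"] = 10
        return states, labels

    def test_planted_road_effect_recovered(self):
        states, labels = self._planted(np.random.default_rng(7))
        out = context_linear_models(states, labels)
        speed = out.loc["speed"]
        assert speed.loc["road_present", "weight"] == speed["weight"].max()
        assert speed.loc["road_present", "sign"] == 1.0

    def test_weights_bounded(self):
        states, labels = self._planted(np.random.default_rng(8))
        out = context_linear_models(states, labels)
        assert ((out["weight"] >= 0) & (out["weight"] <= 1)).all()
        assert set(out.index.get_level_values("metric")) == set(METRICS)

    def test_tod_arrows_reported(self):
        rng = np.random.default_rng(9)
        states, labels = self._planted(rng)
        states["polarization"] = 5 + 4.0 * (labels["time_of_day"] == 2) + rng.normal(0, 0.5, len(states))
        out = context_linear_models(states, labels)
        row = out.loc[("polarization", "time_of_day")]
        assert row["tod_max"] == "evening"
        assert row["weight"] > 0.9
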