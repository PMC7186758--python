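import numpy as np
import pandas as pd
import pytest

from socialspike.behavior import (
    angular_rate_profile,
    approach_bearing,
    compare_focal_vs_others_speed,
    nearest_bee,
    orientation_to_gravity,
    quarter_split,
    relative_body_angle,
    walking_speed,
)
from socialspike.io import TrackTable
from socialspike.synthetic import SimConfig, simulate_colony


def make_table(bees: dict[str, np.ndarray], theta: dict[str, np.ndarray] | None = None):
    """Build a TrackTable from {bee_id: (n, 2) positions}."""
    rows = []
    for bee, xy in bees.items():
        n = len(xy)
        th = theta.get(bee, np.zeros(n)) if theta else np.zeros(n)
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(n),
                    "time_s": np.arange(n) / 10.0,
                    "bee_id": bee,
                    "x_cm": xy[:, 0],
                    "y_cm": xy[:, 1],
                    "theta_deg": th % 360.0,
                }
            )
        )
    return TrackTable(pd.concat(rows, ignore_index=True))


class TestWalkingSpeed:
    def test_stationary_bee_all_zero(self):
        t = make_table({"focal": np.tile([5.0, 5.0], (20, 1))})
        assert (walking_speed(t.bee("focal")).to_numpy() == 0).all()

    def test_one_mm_per_frame_is_one_cm_per_s(self):
        xy = np.cumsum(np.tile([0.1, 0.0], (10, 1)), axis=0)
        sp = walking_speed(make_table({"focal": xy}).bee("focal"))
        assert sp.iloc[0] == 0.0
        assert np.allclose(sp.iloc[1:], 1.0)

    def test_single_frame_warns_empty(self):
        t = make_table({"focal": np.array([[1.0, 1.0]])})
        with pytest.warns(UserWarning):
            assert len(walking_speed(t.bee("focal"))) == 0

    def test_translation_invariance(self, rng):
        xy = rng.uniform(0, 10, size=(50, 2))
        a = walking_speed(make_table({"focal": xy}).bee("focal"))
        b = walking_speed(make_table({"focal": xy + [20.0, -3.0]}).bee("focal"))
        assert np.allclose(a, b)

    def test_mean_go_speed_recovered_from_simulation(self):
        """Nonzero walking speeds in the simulation should average to the
        configured mean go-speed (log-normal draws, reflections preserve
        step length)."""
        cfg = SimConfig(
            duration_s=2000.0, seed=8, n_other_bees=0, mean_speed_cm_s=1.5,
            passive_rate_per_min=0, active_rate_per_min=0,
        )
        tracks, _ = simulate_colony(cfg)
        sp = walking_speed(tracks.bee("focal")).to_numpy()
        go = sp[sp > 1e-9]
        assert len(go) > 2000
        assert abs(go.mean() - 1.5) / 1.5 < 0.05


class TestNearestBee:
    def test_three_four_five(self):
        t = make_table({"focal": np.array([[0.0, 0.0]] * 2), "beeA": np.array([[3.0, 4.0]] * 2)})
        nb = nearest_bee(t)
        assert np.allclose(nb["distance_cm"], 5.0)
        assert (nb["partner_id"] == "beeA").all()

    def test_tie_broken_to_lower_id(self):
        t = make_table(
            {
                "focal": np.array([[0.0, 0.0]]),
                "beeB": np.array([[2.0, 0.0]]),
                "beeA": np.array([[-2.0, 0.0]]),
            }
        )
        assert nearest_bee(t)["partner_id"].iloc[0] == "beeA"

    def test_no_other_bee_undefined(self):
        t = make_table({"focal": np.zeros((5, 2))})
        nb = nearest_bee(t)
        assert nb["distance_cm"].isna().all()

    def test_matches_brute_force_all_pairs(self, main_sim):
        cfg, tracks, _ = main_sim
        nb = nearest_bee(tracks)
        focal = tracks.bee("focal")
        frames = focal.index.to_numpy()[::37]  # subsample for speed
        others = tracks.data[tracks.data["bee_id"] != "focal"]
        for f in frames:
            fx, fy = focal.loc[f, ["x_cm", "y_cm"]]
            sub = others[others["frame"] == f]
            d = np.hypot(sub["x_cm"] - fx, sub["y_cm"] - fy)
            assert nb.loc[f, "distance_cm"] == pytest.approx(d.min())

    def test_two_bees_mutually_nearest(self):
        xy_a = np.array([[1.0, 1.0]] * 3)
        xy_b = np.array([[4.0, 5.0]] * 3)
        t = make_table({"focal": xy_a, "beeA": xy_b})
        d_ab = nearest_bee(t, "focal")["distance_cm"]
        d_ba = nearest_bee(t, "beeA")["distance_cm"]
        assert np.allclose(d_ab, d_ba)


class TestAngles:
    @pytest.mark.parametrize(
        "theta,expected",
        [(270.0, 180.0), (90.0, 0.0), (0.0, 270.0), (180.0, 90.0)],
    )
    def test_gravity_angle_conventions(self, theta, expected):
        # +y is up-slope; pointing down-slope (-y) must read 180 deg
        out = orientation_to_gravity(pd.Series([theta]))
        assert out.iloc[0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "focal,other,expected", [(40.0, 40.0, 0.0), (10.0, 190.0, 180.0), (30.0, 300.0, 270.0)]
    )
    def test_relative_body_angle(self, focal, other, expected):
        out = relative_body_angle(pd.Series([focal]), pd.Series([other]))
        assert out.iloc[0] == pytest.approx(expected)

    def test_approach_bearing_straight_ahead(self):
        focal = pd.DataFrame({"x_cm": [0.0], "y_cm": [0.0], "theta_deg": [90.0]})
        near = pd.DataFrame({"x_cm": [0.0], "y_cm": [3.0]})
        assert approach_bearing(focal, near).iloc[0] == pytest.approx(0.0)


class TestAngularProfile:
    def test_uniform_rate_flat_profile(self, rng):
        ang = rng.uniform(0, 360, 5000)
        prof = angular_rate_profile(ang, np.full(5000, 7.0))
        assert np.allclose(prof["mean_rate_hz"].dropna(), 7.0)

    def test_rate_localized_to_one_bin(self):
        prof = angular_rate_profile(np.full(50, 5.0), np.full(50, 3.0))
        assert prof.loc[0, "mean_rate_hz"] == pytest.approx(3.0)
        assert prof["mean_rate_hz"].iloc[1:].isna().all()

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            angular_rate_profile(np.array([0.0]), np.array([1.0]), bin_deg=7.0)

    def test_rotation_shifts_profile_by_whole_bins(self, rng):
        ang = rng.uniform(0, 360, 2000)
        rates = rng.exponential(5.0, 2000)
        p0 = angular_rate_profile(ang, rates)["mean_rate_hz"].to_numpy()
        p3 = angular_rate_profile((ang + 30.0) % 360, rates)["mean_rate_hz"].to_numpy()
        assert np.allclose(np.roll(p0, 3), p3, equal_nan=True)


class TestQuarterSplit:
    def test_exact_division(self):
        parts = quarter_split(np.arange(400))
        assert [len(p) for p in parts] == [100, 100, 100, 100]

    def test_remainder_goes_last(self):
        parts = quarter_split(np.arange(403))
        assert [len(p) for p in parts] == [100, 100, 100, 103]

    def test_concatenation_recovers_original(self, rng):
        x = rng.normal(size=157)
        assert np.array_equal(np.concatenate(quarter_split(x)), x)


class TestSpeedComparison:
    def test_identical_samples_statistic_zero(self):
        x = np.arange(30, dtype=float)
        res = compare_focal_vs_others_speed(x, x.copy())
        assert res.statistic == 0.0 and res.p == 1.0

    def test_doubled_speeds_detected(self, rng):
        base = rng.lognormal(0.0, 0.5, size=1000)
        res = compare_focal_vs_others_speed(2 * base, rng.lognormal(0.0, 0.5, size=1000))
        assert res.p < 1e-3

    def test_null_rejection_rate_near_alpha(self):
        """Same locomotion distribution for focal and comparison bees:
        rejections at 0.05 should occur at roughly the nominal rate."""
        rng = np.random.default_rng(1234)
        rej = sum(
            compare_focal_vs_others_speed(
                rng.lognormal(0, 0.5, 200), rng.lognormal(0, 0.5, 200)
            ).p
            <= 0.05
            for _ in range(200)
        )
        assert 0.01 <= rej / 200 <= 0.10
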