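import numpy as np
import pandas as pd
import pytest

import schoolkit as sk
from schoolkit.pairwise_metrics import (
    interindividual_distance,
    joint_distance_angle_distribution,
    nearest_neighbor_distance,
    nn_pair_angle,
    pair_angle,
    pair_distance,
    speed_metric_correlation,
    wall_occupancy_excess,
)


def make_static_trial(positions, headings, n_frames=10, arena=None, cohort=None):
    """A trial whose fish hold fixed positions/headings (radians)."""
    arena = arena or sk.ArenaGeometry(radius_cm=17.0)
    cohort = cohort or sk.CohortSpec("surface", 70, 2.2)
    frames = np.arange(n_frames, dtype=np.int64)
    t = frames / 30.0
    tracks = [
        sk.FishTrack(str(i), frames, t,
                     np.tile(np.asarray(p, dtype=float), (n_frames, 1)),
                     np.full(n_frames, h))
        for i, (p, h) in enumerate(zip(positions, headings))
    ]
    return sk.TrialGroup("static", tracks, arena, cohort)


class TestPairDistance:
    def test_three_four_five(self):
        trial = make_static_trial([(0, 0), (3, 4)], [0, 0])
        d = pair_distance(trial)
        assert (d["pair_distance"] == 5.0).all()

    def test_coincident_fish(self):
        trial = make_static_trial([(1, 1), (1, 1)], [0, 1])
        assert (pair_distance(trial)["pair_distance"] == 0.0).all()

    def test_bounded_by_arena_diameter(self, small_trial):
        d = pair_distance(small_trial, unit="tank_radii")
        assert d["pair_distance"].max() <= 2.0 + 1e-9


class TestPairAngle:
    @pytest.mark.parametrize("h1,h2,expected", [
        (0.0, np.pi / 2, 90.0),
        (np.radians(10), np.radians(350), 20.0),
        (0.3, 0.3, 0.0),
        (0.0, np.pi, 180.0),
    ])
    def test_folding_into_0_180(self, h1, h2, expected):
        trial = make_static_trial([(0, 0), (1, 0)], [h1, h2])
        assert pair_angle(trial)["pair_angle"].iloc[0] == pytest.approx(expected)

    def test_symmetric_under_fish_swap(self):
        trial = make_static_trial([(0, 0), (1, 0)], [0.4, 2.9])
        swapped = make_static_trial([(1, 0), (0, 0)], [2.9, 0.4])
        assert pair_angle(trial)["pair_angle"].iloc[0] == pytest.approx(
            pair_angle(swapped)["pair_angle"].iloc[0])


class TestNearestNeighbor:
    def test_collinear_three_fish(self):
        trial = make_static_trial([(0, 0), (3, 0), (5, 0)], [0, 0, 0])
        nnd = nearest_neighbor_distance(trial)
        per_fish = nnd.groupby("fish_id")["nnd"].first()
        assert list(per_fish[["0", "1", "2"]]) == [3.0, 2.0, 2.0]

    def test_two_fish_nnd_equals_pair_distance(self):
        trial = make_static_trial([(0, 0), (3, 4)], [0, 1])
        nnd = nearest_neighbor_distance(trial)
        assert (nnd["nnd"] == 5.0).all()
        assert (nn_pair_angle(trial)["nn_pair_angle"]
                == pair_angle(trial)["pair_angle"].iloc[0]).all()

    def test_nnd_never_exceeds_any_iid(self, small_trial):
        nnd = nearest_neighbor_distance(small_trial).set_index(
            ["frame", "fish_id"])["nnd"]
        iid = interindividual_distance(small_trial).rename(
            columns={"focal_id": "fish_id"})
        min_iid = iid.groupby(["frame", "fish_id"])["iid"].min()
        np.testing.assert_allclose(nnd.sort_index(), min_iid.sort_index())

    def test_schooling_closer_than_null(self, schooling_trials, small_null_trials):
        school = np.median([sk.trial_metric_summary(t)["nnd_median"]
                            for t in schooling_trials[:4]])
        null = np.median([sk.trial_metric_summary(t)["nnd_median"]
                          for t in small_null_trials])
        assert school < null


class TestInterindividualDistance:
    def test_focal_zero_distances(self):
        trial = make_static_trial([(0, 0), (3, 0), (5, 0)], [0, 0, 0])
        iid = interindividual_distance(trial)
        focal0 = iid[(iid["focal_id"] == "0") & (iid["frame"] == 0)]
        assert sorted(focal0["iid"]) == [3.0, 5.0]

    def test_five_fish_have_four_iids_each(self, small_trial):
        iid = interindividual_distance(small_trial)
        counts = iid.groupby(["frame", "focal_id"]).size()
        assert (counts == small_trial.n_fish - 1).all()

    def test_mean_iid_equals_mean_pair_distance(self, small_trial):
        # every unordered pair appears twice among ordered focal IIDs
        iid = interindividual_distance(small_trial)["iid"].mean()
        pd_ = pair_distance(small_trial)["pair_distance"].mean()
        assert iid == pytest.approx(pd_)


class TestNNPairAngle:
    def test_independent_uniform_headings_median_near_90(self, rng):
        n_frames = 4000
        frames = np.arange(n_frames, dtype=np.int64)
        t = frames / 30.0
        arena = sk.ArenaGeometry(radius_cm=17.0)
        cohort = sk.CohortSpec("surface", 70, 2.2)
        tracks = [
            sk.FishTrack(str(i), frames, t,
                         np.tile([float(i), 0.0], (n_frames, 1)),
                         np.unwrap(rng.uniform(-np.pi, np.pi, n_frames)))
            for i in range(3)
        ]
        trial = sk.TrialGroup("uniform", tracks, arena, cohort)
        med = float(np.median(nn_pair_angle(trial)["nn_pair_angle"]))
        assert med == pytest.approx(90.0, abs=4.0)

    def test_schooling_more_aligned_than_null(self, schooling_trials,
                                              small_null_trials):
        school = np.median([sk.trial_metric_summary(t)["nn_pair_angle_median"]
                            for t in schooling_trials[:4]])
        null = np.median([sk.trial_metric_summary(t)["nn_pair_angle_median"]
                          for t in small_null_trials])
        assert school < 90.0
        assert school < null


class TestJointDistribution:
    def test_single_record_single_bin(self):
        rec = pd.DataFrame({"pair_distance": [1.0], "pair_angle": [45.0]})
        h, _, _ = joint_distance_angle_distribution(
            rec, [0, 2, 4], [0, 90, 180])
        assert h[0, 0] == 1.0
        assert h.sum() == 1.0

    def test_mass_sums_to_one_with_covering_bins(self, small_trial):
        rec = pd.merge(pair_distance(small_trial), pair_angle(small_trial),
                       on=["frame", "focal_id", "neighbor_id"])
        h, _, _ = joint_distance_angle_distribution(
            rec, np.linspace(0, 40, 9), np.linspace(0, 180, 10))
        assert h.sum() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            joint_distance_angle_distribution(
                pd.DataFrame({"pair_distance": [], "pair_angle": []}),
                [0, 1], [0, 90])

    def test_schooling_mode_at_short_distance_small_angle(self, schooling_analysis):
        joint, d_edges, a_edges = schooling_analysis["joint_distribution"]
        i, j = np.unravel_index(np.argmax(joint), joint.shape)
        # mode within the closest third of distances and smallest third of angles
        assert d_edges[i] < d_edges[-1] / 3
        assert a_edges[j] < 60.0


class TestSpeedCorrelation:
    def test_metric_equal_to_speed_gives_rho_one(self, small_null_trials,
                                                 monkeypatch):
        import schoolkit.pairwise_metrics as pm

        speeds = {id(t): 1.0 + i for i, t in enumerate(small_null_trials)}
        monkeypatch.setattr(pm, "mean_swim_speed",
                            lambda t, smooth=True: speeds[id(t)])
        monkeypatch.setitem(pm._METRIC_FUNCS, "nnd",
                            lambda t, unit: pd.Series([speeds[id(t)]]))
        rho, p = speed_metric_correlation(small_null_trials, "nnd")
        assert rho == pytest.approx(1.0)

    def test_sign_flips_with_metric_sign(self, small_null_trials, monkeypatch):
        import schoolkit.pairwise_metrics as pm

        speeds = {id(t): 1.0 + i for i, t in enumerate(small_null_trials)}
        monkeypatch.setattr(pm, "mean_swim_speed",
                            lambda t, smooth=True: speeds[id(t)])
        monkeypatch.setitem(pm._METRIC_FUNCS, "nnd",
                            lambda t, unit: pd.Series([-speeds[id(t)]]))
        rho, _ = speed_metric_correlation(small_null_trials, "nnd")
        assert rho == pytest.approx(-1.0)

    def test_constant_metric_reports_nan(self, small_null_trials, monkeypatch):
        import schoolkit.pairwise_metrics as pm

        monkeypatch.setitem(pm._METRIC_FUNCS, "nnd",
                            lambda t, unit: pd.Series([1.0]))
        rho, p = speed_metric_correlation(small_null_trials, "nnd")
        assert np.isnan(rho) and np.isnan(p)

    def test_requires_three_trials(self, small_null_trials):
        with pytest.raises(ValueError):
            speed_metric_correlation(small_null_trials[:2], "nnd")


class TestRigidInvariance:
    def test_metrics_invariant_under_rotation_translation(self, small_trial):
        rotated = sk.rotate_trial(small_trial, 0.9)
        for func in (lambda t: pair_distance(t)["pair_distance"],
                     lambda t: pair_angle(t)["pair_angle"],
                     lambda t: nearest_neighbor_distance(t)["nnd"],
                     lambda t: nn_pair_angle(t)["nn_pair_angle"]):
            np.testing.assert_allclose(func(rotated), func(small_trial),
                                       atol=1e-9)


def test_wall_occupancy_excess_orders_presets(asocial_trials, small_null_trials):
    wall = np.mean([wall_occupancy_excess(t) for t in asocial_trials[:4]])
    null = np.mean([wall_occupancy_excess(t) for t in small_null_trials])
    assert wall > null
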