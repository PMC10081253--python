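import numpy as np
import pytest

import schoolkit as sk
from schoolkit.focal_maps import (
    MapAccumulator,
    PairObservations,
    PolarGrid,
    density_map,
    difference_map,
    focal_frame_transform,
    force_map,
    iter_pair_observations,
    map_to_dataframe,
)
from schoolkit.kinematics import trial_kinematics


def make_obs(x, y, f_speed=None, f_turn=None, alpha=None, dphi=None):
    x = np.asarray(x, dtype=float)
    zeros = np.zeros_like(x)
    ints = np.zeros(len(x), dtype=np.int32)
    return PairObservations(
        x=x, y=np.asarray(y, dtype=float),
        f_speed=zeros if f_speed is None else np.asarray(f_speed, float),
        f_turn=zeros if f_turn is None else np.asarray(f_turn, float),
        alpha=zeros if alpha is None else np.asarray(alpha, float),
        dphi=zeros if dphi is None else np.asarray(dphi, float),
        focal_trial=ints, focal_fish=ints, neighbor_trial=ints,
        neighbor_fish=ints,
    )


class TestPolarGrid:
    def test_default_radial_edges(self):
        assert PolarGrid().radial_edges == (0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5)

    def test_bin_area_formula(self):
        grid = PolarGrid()
        # outermost ring 0.4-0.5 with 12 sectors
        expected = np.pi * (0.5**2 - 0.4**2) / 12
        assert grid.bin_area[-1, 0] == pytest.approx(expected)
        assert grid.bin_area[-1, 0] == pytest.approx(0.02356, abs=5e-5)
        assert grid.bin_area.sum() == pytest.approx(np.pi * 0.25)

    def test_assignment_quadrants(self):
        grid = PolarGrid()
        # directly ahead, right, behind, left at 0.25 tank radii
        ring, sector = grid.assign([0.0, 0.25, 0.0, -0.25],
                                   [0.25, 0.0, -0.25, 0.0])
        assert list(ring) == [4, 4, 4, 4]  # ring 0.2-0.3
        assert list(sector) == [0, 3, 6, 9]

    def test_out_of_range_flagged(self):
        grid = PolarGrid()
        ring, _ = grid.assign([0.6], [0.0])
        assert ring[0] == -1

    def test_half_plane_sector_signs(self):
        grid = PolarGrid()
        ahead = grid.sector_sign_ahead
        right = grid.sector_sign_right
        assert list(np.where(ahead > 0)[0]) == [0, 1, 2, 9, 10, 11]
        assert list(np.where(right > 0)[0]) == [0, 1, 2, 3, 4, 5]

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            PolarGrid(radial_edges=(0.05, 0.1))
        with pytest.raises(ValueError):
            PolarGrid(radial_edges=(0, 0.2, 0.1))


class TestFocalFrameTransform:
    def test_neighbor_ahead(self, arena):
        x, y = focal_frame_transform([0.0, 0.0], np.pi / 2,
                                     [0.0, 0.2 * arena.radius_cm], arena)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert y == pytest.approx(0.2)

    def test_neighbor_right(self, arena):
        # focal faces +y; its right is +x
        x, y = focal_frame_transform([0.0, 0.0], np.pi / 2,
                                     [0.3 * arena.radius_cm, 0.0], arena)
        assert x == pytest.approx(0.3)
        assert y == pytest.approx(0.0, abs=1e-12)

    def test_global_rotation_invariance(self, arena, rng):
        focal = rng.normal(size=2) * 3
        nb = rng.normal(size=2) * 3
        phi = 0.8
        x0, y0 = focal_frame_transform(focal, phi, nb, arena)
        for angle in (0.5, 2.0, -1.3):
            c, s = np.cos(angle), np.sin(angle)
            rot = np.array([[c, -s], [s, c]])
            x1, y1 = focal_frame_transform(rot @ focal, phi + angle,
                                           rot @ nb, arena)
            assert x1 == pytest.approx(x0)
            assert y1 == pytest.approx(y0)


class TestDensityMap:
    def test_all_mass_in_one_bin(self):
        grid = PolarGrid()
        obs = make_obs([0.0] * 10, [0.25] * 10)
        fmap = density_map(obs, grid)
        area = grid.bin_area[4, 0]
        assert fmap.values[4, 0] == pytest.approx(1.0 / area)
        assert np.sum(np.nan_to_num(fmap.values)) == pytest.approx(1.0 / area)

    def test_normalization_identity(self, small_trial):
        """sum(value x area) = fraction of observations within 0.5 tank radii."""
        grid = PolarGrid()
        chunks = list(iter_pair_observations([small_trial], mode="within"))
        fmap = density_map(chunks, grid)
        mass = np.sum(fmap.values * grid.bin_area)
        r = np.concatenate([c.r for c in chunks])
        assert mass == pytest.approx(np.mean(r < 0.5), abs=1e-12)

    def test_no_observations_rejected(self):
        with pytest.raises(ValueError):
            density_map(make_obs([], []), PolarGrid())


class TestForceMap:
    def test_constant_force_fills_defined_bins(self):
        grid = PolarGrid(n_sectors=4)
        obs = make_obs([0.0, 0.2, -0.1], [0.25, 0.0, -0.2],
                       f_speed=[1.5, 1.5, 1.5])
        fmap = force_map(obs, grid, kind="speeding")
        defined = fmap.counts > 0
        assert np.all(fmap.values[defined] == 1.5)
        assert np.all(np.isnan(fmap.values[~defined]))

    def test_empty_bins_are_nan_not_zero(self):
        fmap = force_map(make_obs([0.0], [0.25], f_turn=[2.0]),
                         PolarGrid(), kind="turning")
        assert np.isnan(fmap.values).sum() == fmap.values.size - 1

    def test_normalization_divides_values(self):
        obs = make_obs([0.0], [0.25], f_speed=[3.0])
        fmap = force_map(obs, PolarGrid(), kind="speeding", normalize_by=6.0)
        assert np.nanmax(fmap.values) == pytest.approx(0.5)

    def test_mirror_transposes_turning_map_and_negates_it(self, small_trial):
        grid = PolarGrid()
        real = force_map(iter_pair_observations([small_trial], mode="within"),
                         grid, kind="turning")
        mirrored = force_map(
            iter_pair_observations([sk.mirror_trial(small_trial)],
                                   mode="within"),
            grid, kind="turning")
        # left-right mirror: sector s -> n_sectors-1-s, value -> -value
        flipped = mirrored.values[:, ::-1]
        ok = np.isfinite(real.values) & np.isfinite(flipped)
        np.testing.assert_allclose(flipped[ok], -real.values[ok], atol=1e-9)

    def test_rotation_leaves_maps_invariant(self, small_trial):
        grid = PolarGrid()
        a = force_map(iter_pair_observations([small_trial], mode="within"),
                      grid, kind="speeding")
        b = force_map(
            iter_pair_observations([sk.rotate_trial(small_trial, 1.7)],
                                   mode="within"),
            grid, kind="speeding")
        ok = np.isfinite(a.values)
        np.testing.assert_allclose(b.values[ok], a.values[ok], atol=1e-9)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestDifferenceMap:
    def test_identical_maps_give_zero(self, small_trial):
        fmap = density_map(iter_pair_observations([small_trial], mode="within"))
        diff = difference_map(fmap, fmap)
        ok = np.isfinite(diff.values)
        assert np.all(diff.values[ok] == 0.0)

    def test_mock_all_zero_returns_real(self):
        grid = PolarGrid()
        real = force_map(make_obs([0.0], [0.25], f_speed=[2.0]), grid)
        mock = force_map(make_obs([0.0], [0.25], f_speed=[0.0]), grid)
        diff = difference_map(real, mock)
        assert diff.values[4, 0] == pytest.approx(2.0)

    def test_grid_or_kind_mismatch_rejected(self):
        obs = make_obs([0.0], [0.25], f_speed=[1.0])
        a = force_map(obs, PolarGrid(), kind="speeding")
        b = force_map(obs, PolarGrid(n_sectors=8), kind="speeding")
        with pytest.raises(ValueError):
            difference_map(a, b)
        c = force_map(obs, PolarGrid(), kind="turning")
        with pytest.raises(ValueError):
            difference_map(a, c)

    def test_undefined_where_either_parent_undefined(self):
        grid = PolarGrid()
        a = force_map(make_obs([0.0, 0.2], [0.25, 0.0], f_speed=[1.0, 1.0]), grid)
        b = force_map(make_obs([0.0], [0.25], f_speed=[0.5]), grid)
        diff = difference_map(a, b)
        assert np.isfinite(diff.values[4, 0])
        assert np.isnan(diff.values[4, 3])  # defined in a only

    def test_null_cohort_difference_density_near_zero(self, small_null_trials):
        """Real minus cross-trial-pair mock density for independent walkers is
        zero within Monte-Carlo error in every well-sampled bin."""
        grid = PolarGrid()
        real = density_map(
            iter_pair_observations(small_null_trials, mode="within"), grid)
        mock = density_map(
            iter_pair_observations(small_null_trials, mode="cross"), grid)
        diff = difference_map(real, mock)
        ok = (real.counts > 50) & (mock.counts > 50)
        # SE of a per-bin density from counting statistics of the real map
        se = np.sqrt(np.maximum(real.counts, 1)) / real.counts.sum() \
            / grid.bin_area
        assert np.all(np.abs(diff.values[ok]) < 5 * se[ok])


def test_map_dataframe_round_trip(small_trial):
    fmap = density_map(iter_pair_observations([small_trial], mode="within"))
    df = map_to_dataframe(fmap)
    assert len(df) == fmap.values.size
    back = df["value"].to_numpy().reshape(fmap.grid.shape)
    ok = np.isfinite(fmap.values)
    np.testing.assert_allclose(back[ok], fmap.values[ok])


def test_accumulator_emits_same_maps_as_single_calls(small_null_trials):
    grid = PolarGrid()
    chunks = list(iter_pair_observations(small_null_trials[:2], mode="cross"))
    acc = MapAccumulator(grid)
    for c in chunks:
        acc.add(c)
    d1, d2 = acc.density(), density_map(chunks, grid)
    np.testing.assert_allclose(np.nan_to_num(d1.values),
                               np.nan_to_num(d2.values))
    f1, f2 = acc.force("turning"), force_map(chunks, grid, kind="turning")
    np.testing.assert_allclose(np.nan_to_num(f1.values),
                               np.nan_to_num(f2.values))
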