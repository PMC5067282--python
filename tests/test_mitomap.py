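"""Mitochondrial distribution: segmentation, pixel shells, MPM/Mito60, gaps."""

import numpy as np
import pytest

from mitoarbor.mitomap import (
    CumulativeDistribution,
    LabeledImage,
    MitochondrionSet,
    axonal_density,
    cumulative_from_positions,
    mito60,
    mito_sholl,
    mitochondrial_index,
    mpm,
    occupancy_gaps,
    occupancy_gaps_from_mask,
    relative_positions,
    segment,
)
from mitoarbor.morphology import RadialProfile, UndefinedValueError
from mitoarbor.synthetic import truncated_exponential_quantile


class TestSegment:
    def test_two_level_image_otsu(self):
        img = np.zeros((20, 20))
        img[5:10, 5:10] = 100.0
        mask = segment(LabeledImage(img, 0.1, "mitochondria"))
        np.testing.assert_array_equal(mask, img == 100.0)

    def test_fixed_threshold_above_max_is_empty(self):
        img = np.random.default_rng(0).uniform(0, 50, (10, 10))
        assert not segment(img, "fixed", threshold=60.0).any()

    def test_constant_image_otsu_advises_fixed(self):
        with pytest.raises(ValueError, match="fixed"):
            segment(np.full((5, 5), 3.0))

    def test_fixed_requires_threshold(self):
        with pytest.raises(ValueError):
            segment(np.zeros((5, 5)), "fixed")


class TestMitoSholl:
    def test_single_pixel_lands_in_its_distance_shell(self):
        mask = np.zeros((20, 20), dtype=bool)
        # pixel at distance sqrt(7^2 + (1.8)^2) ≈ 7.22 from fractional center
        mask[10, 17] = True
        profile = mito_sholl(mask, soma_center=(10.0, 9.8), shell_width=1.0)
        assert profile.counts[7] == 1
        assert profile.counts.sum() == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_conserves_mass_and_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 64)) < 0.2
        center = (rng.uniform(0, 47), rng.uniform(0, 63))
        width = rng.choice([1.0, 2.0, 3.0])
        profile = mito_sholl(mask, center, width)
        assert profile.counts.sum() == mask.sum()
        # brute force: per-pixel loop with explicit binning
        expected = np.zeros_like(profile.counts)
        for r in range(mask.shape[0]):
            for c in range(mask.shape[1]):
                if mask[r, c]:
                    d = np.hypot(r - center[0], c - center[1])
                    expected[int(d // width)] += 1
        np.testing.assert_array_equal(profile.counts, expected)

    def test_empty_mask_gives_zero_profile(self):
        profile = mito_sholl(np.zeros((10, 10), dtype=bool), (5, 5))
        assert profile.counts.sum() == 0


class TestMPM:
    def test_all_mass_innermost_shell(self):
        profile = RadialProfile([0.0, 1.0, 2.0, 3.0], [10.0, 0.0, 0.0], "pixels")
        cdf = mpm(profile, max_extent=10.0)
        # fraction is 1 from the first shell edge onward
        assert cdf.cumulative_fraction[1] == 1.0
        assert cdf.cumulative_fraction[-1] == 1.0

    def test_uniform_profile_is_linear(self):
        profile = RadialProfile(np.arange(11.0), np.ones(10), "pixels")
        cdf = mpm(profile, max_extent=10.0)
        np.testing.assert_allclose(
            cdf.cumulative_fraction, cdf.normalized_distance, atol=1e-12
        )

    def test_zero_mass_undefined(self):
        profile = RadialProfile([0.0, 1.0], [0.0], "pixels")
        with pytest.raises(UndefinedValueError):
            mpm(profile, 5.0)

    def test_max_extent_must_cover_mass(self):
        profile = RadialProfile([0.0, 5.0, 10.0], [0.0, 3.0], "pixels")
        with pytest.raises(ValueError):
            mpm(profile, 7.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_curve_non_decreasing_and_ends_at_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=20).astype(float)
        counts[rng.integers(0, 20)] += 1  # ensure mass
        profile = RadialProfile(np.arange(21.0), counts, "pixels")
        cdf = mpm(profile, max_extent=30.0)
        assert np.all(np.diff(cdf.cumulative_fraction) >= 0)
        assert cdf.cumulative_fraction[-1] == 1.0


class TestMito60:
    def test_uniform_cdf_gives_060(self):
        grid = np.linspace(0, 1, 50)
        assert mito60(CumulativeDistribution(grid, grid)) == pytest.approx(0.6)

    @pytest.mark.parametrize("tau", [0.15, 0.3, 0.6])
    def test_truncated_exponential_closed_form(self, tau):
        # exact CDF of the truncated-exponential density evaluated on a grid
        grid = np.linspace(0, 1, 2001)
        cf = (1 - np.exp(-grid / tau)) / (1 - np.exp(-1 / tau))
        cdf = CumulativeDistribution(grid, cf / cf[-1])
        expected = truncated_exponential_quantile(0.6, tau)
        assert mito60(cdf) == pytest.approx(expected, abs=1e-4)

    def test_proximal_shift_decreases_mito60(self):
        grid = np.linspace(0, 1, 101)
        uniform = CumulativeDistribution(grid, grid)
        proximal = CumulativeDistribution(grid, np.sqrt(grid))  # mass toward 0
        assert mito60(proximal) < mito60(uniform)

    def test_analytic_value_for_tau_03(self):
        assert truncated_exponential_quantile(0.6, 0.3) == pytest.approx(0.259, abs=5e-4)


class TestMitochondrialIndex:
    def test_identical_masks_give_one(self):
        mask = np.random.default_rng(1).random((30, 30)) < 0.3
        assert mitochondrial_index(mask, mask) == 1.0

    def test_empty_mito_gives_zero(self):
        dend = np.ones((10, 10), dtype=bool)
        assert mitochondrial_index(np.zeros_like(dend), dend) == 0.0

    def test_known_painted_areas(self):
        dend = np.zeros((20, 20), dtype=bool)
        dend[:, :10] = True  # 200 px
        mito = np.zeros_like(dend)
        mito[:5, :10] = True  # 50 px inside the dendrite mask
        mito[:5, 15:] = True  # outside — must not count
        assert mitochondrial_index(mito, dend) == pytest.approx(50 / 200)

    def test_zero_dendrite_area_undefined(self):
        with pytest.raises(UndefinedValueError):
            mitochondrial_index(np.ones((5, 5), bool), np.zeros((5, 5), bool))


class TestOccupancyGaps:
    def test_full_tiling_gives_zero(self):
        mitos = MitochondrionSet.from_arrays([5.0, 15.0, 25.0, 35.0], 10.0)
        fraction, gaps = occupancy_gaps(40.0, mitos)
        assert fraction == 0.0
        assert gaps == []

    def test_single_centered_mito_on_40um_path(self):
        mitos = MitochondrionSet.from_arrays([20.0], 10.0)
        fraction, gaps = occupancy_gaps(40.0, mitos, step=0.1)
        assert fraction == pytest.approx(0.75)
        assert len(gaps) == 2

    def test_empty_set_is_one_full_gap(self):
        fraction, gaps = occupancy_gaps(30.0, MitochondrionSet())
        assert fraction == 1.0
        assert gaps == [(0.0, 30.0)]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_interval_union_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        length = 120.0
        mitos = MitochondrionSet.from_arrays(
            rng.uniform(0, length, 25), rng.uniform(0.5, 3.0, 25)
        )
        fraction, _ = occupancy_gaps(length, mitos, step=0.1)
        samples = np.arange(0, length, 0.1)
        covered = np.zeros(len(samples), dtype=bool)
        for m in mitos.items:
            covered |= (samples >= m.centroid_path_position - m.length / 2) & (
                samples < m.centroid_path_position + m.length / 2
            )
        assert fraction == pytest.approx(np.mean(~covered))

    def test_fraction_non_increasing_as_mitos_added(self, rng):
        length = 80.0
        positions = rng.uniform(0, length, 15)
        prev = 1.0
        for k in range(1, 16):
            mitos = MitochondrionSet.from_arrays(positions[:k], 2.0)
            fraction, _ = occupancy_gaps(length, mitos)
            assert fraction <= prev + 1e-12
            prev = fraction

    def test_image_mode_agrees_with_interval_mode(self):
        # straight horizontal path over a mask with one painted stretch
        mask = np.zeros((9, 400), dtype=bool)
        mask[4, 150:251] = True  # 15.0–25.0 μm at 0.1 μm/px
        path = np.array([[0.4, 0.0], [0.4, 39.9]])  # μm (row, col)
        path_um = np.array([[0.4, 0.0], [0.4, 39.9]])
        fraction, _ = occupancy_gaps_from_mask(
            path_um, mask, pixel_size=0.1, radius=0.5, step=0.1
        )
        assert fraction == pytest.approx(0.75, abs=0.03)


class TestAxonalStatistics:
    def test_density_direct_arithmetic(self):
        mitos = MitochondrionSet.from_arrays(np.linspace(1, 50, 12), 1.0)
        assert axonal_density(52.0, mitos) == pytest.approx(2.3077, abs=1e-4)

    def test_zero_mitos_zero_density(self):
        assert axonal_density(52.0, MitochondrionSet()) == 0.0

    def test_density_homogeneity(self):
        mitos = MitochondrionSet.from_arrays(np.linspace(1, 50, 12), 1.0)
        doubled = MitochondrionSet.from_arrays(np.linspace(1, 100, 24), 1.0)
        assert axonal_density(52.0, mitos) == pytest.approx(
            axonal_density(104.0, doubled)
        )

    def test_relative_positions_endpoints(self):
        mitos = MitochondrionSet.from_arrays([25.0, 100.0], 1.0)
        np.testing.assert_allclose(relative_positions(100.0, mitos), [0.25, 1.0])

    def test_uniform_positions_ks_close_to_uniform_law(self, rng):
        from scipy.stats import kstest

        positions = rng.uniform(0, 300.0, 5000)
        rel = relative_positions(300.0, MitochondrionSet.from_arrays(positions, 1.0))
        assert kstest(rel, "uniform").statistic < 0.03


def test_cumulative_from_positions_step_at_single_radius():
    cdf = cumulative_from_positions([30.0, 30.0, 30.0], max_extent=100.0)
    assert mito60(cdf) == pytest.approx(0.3, abs=1e-9)
    assert cdf.cumulative_fraction[-1] == 1.0
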