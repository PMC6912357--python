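"""Unit tests for the imaging pipeline stages."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bluesclera import (
    ExposureStack,
    PipelineStageError,
    RegionMask,
    SeedPoints,
    blue_fraction_map,
    blue_percentile,
    compute_bp,
    delineate_sclera,
    grow_region,
    merge_exposures,
    polygon_mask,
    white_normalize,
)

from oracles import percentile_oracle


def _stack(frames, times):
    return ExposureStack(frames=np.asarray(frames, float),
                         exposure_times=np.asarray(times, float))


class TestExposureStack:
    def test_rejects_nonincreasing_times(self):
        frames = np.zeros((2, 2, 2, 3))
        with pytest.raises(ValueError):
            _stack(frames, [1.0, 1.0])
        with pytest.raises(ValueError):
            _stack(frames, [2.0, 1.0])

    def test_rejects_zero_exposure(self):
        with pytest.raises(ValueError):
            _stack(np.zeros((1, 2, 2, 3)), [0.0])

    def test_rejects_empty_stack(self):
        with pytest.raises(ValueError):
            _stack(np.zeros((0, 2, 2, 3)), [])


class TestMergeExposures:
    def test_single_frame_is_pixel_over_time(self):
        frames = np.full((1, 2, 2, 3), 0.5)
        merged = merge_exposures(_stack(frames, [0.25]))
        assert np.allclose(merged, 2.0)

    def test_consistent_bracketing_recovers_radiance(self):
        base = np.full((3, 4, 3), 0.2)
        stack = _stack([base, 2 * base], [1.0, 2.0])
        assert np.allclose(merge_exposures(stack), 0.2)

    def test_saturated_samples_excluded_hand_computed(self):
        # 1x4 image, two frames t=(1, 4); second frame saturates pixels 0-1.
        f1 = np.array([[[0.5] * 3, [0.25] * 3, [0.2] * 3, [0.3] * 3]])
        f2 = np.array([[[1.0] * 3, [1.0] * 3, [0.8] * 3, [0.9] * 3]])
        merged = merge_exposures(_stack([f1, f2], [1.0, 4.0]))
        # saturated second samples carry zero weight -> first-frame estimate
        assert np.allclose(merged[0, 0], 0.5)
        assert np.allclose(merged[0, 1], 0.25)
        # consistent pair: both estimates agree
        assert np.allclose(merged[0, 2], 0.2)
        # inconsistent pair, hand-computed hat-weighted mean:
        # w(0.3)=0.28, w(0.9)=0.08 -> (0.28*0.3 + 0.08*0.225)/0.36
        assert np.allclose(merged[0, 3], (0.28 * 0.3 + 0.08 * 0.225) / 0.36)

    def test_all_saturated_falls_back_to_shortest_exposure(self):
        f = np.ones((1, 1, 3))
        merged = merge_exposures(_stack([f, f], [1.0, 2.0]))
        assert np.allclose(merged, 1.0)  # p/t of the shortest frame

    def test_all_dark_falls_back_to_longest_exposure(self):
        f1 = np.full((1, 1, 3), 0.001)
        f2 = np.full((1, 1, 3), 0.004)
        merged = merge_exposures(_stack([f1, f2], [1.0, 4.0]))
        assert np.allclose(merged, 0.001)


class TestGrowRegion:
    def test_uniform_image_fills_everything(self):
        image = np.full((8, 11, 3), 0.4)
        region = grow_region(image, (3, 3), tolerance=0.01)
        assert region.mask.all()
        assert region.pixel_count == 8 * 11

    def test_two_color_image_stops_at_chromaticity_gap(self):
        image = np.full((6, 10, 3), 0.4)
        image[:, 5:] = [0.8, 0.1, 0.1]
        region = grow_region(image, (0, 0), tolerance=0.05)
        expected = np.zeros((6, 10), dtype=bool)
        expected[:, :5] = True
        assert np.array_equal(region.mask, expected)

    def test_zero_sum_seed_rejected(self):
        image = np.zeros((4, 4, 3))
        image[0, 0] = 1.0
        with pytest.raises(ValueError, match="zero-sum"):
            grow_region(image, (2, 2), tolerance=0.1)

    def test_out_of_bounds_seed_rejected(self):
        with pytest.raises(ValueError):
            grow_region(np.ones((4, 4, 3)), (4, 0), tolerance=0.1)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            grow_region(np.ones((4, 4, 3)), (0, 0), tolerance=0.0)


class TestWhiteNormalize:
    def test_patch_mean_maps_to_unit_white(self):
        rng = np.random.default_rng(0)
        image = rng.uniform(0.1, 0.9, size=(6, 6, 3))
        patch = RegionMask(mask=np.arange(36).reshape(6, 6) < 6, method="patch")
        out = white_normalize(image, patch)
        assert np.allclose(out[patch.mask].mean(axis=0), 1.0)

    def test_known_gains_arithmetic(self):
        image = np.zeros((2, 2, 3))
        image[0, 0] = [0.5, 0.4, 0.25]
        image[0, 1] = [0.5, 0.4, 0.25]
        image[1, 0] = [0.25, 0.2, 0.125]
        image[1, 1] = [0.1, 0.1, 0.1]
        patch = RegionMask(mask=np.array([[True, True], [False, False]]),
                           method="patch")
        out = white_normalize(image, patch)
        assert np.allclose(out[1, 0], [0.5, 0.5, 0.5])

    def test_gain_premultiplication_cancels(self):
        rng = np.random.default_rng(1)
        image = rng.uniform(0.1, 0.9, size=(5, 5, 3))
        patch = RegionMask(mask=rng.random((5, 5)) < 0.4, method="patch")
        gains = np.array([2.0, 1.0, 0.5])
        assert np.allclose(white_normalize(image * gains, patch),
                           white_normalize(image, patch), atol=1e-9)

    def test_zero_patch_mean_rejected(self):
        image = np.zeros((2, 2, 3))
        image[..., 0] = 0.5  # green/blue identically zero
        patch = RegionMask(mask=np.ones((2, 2), bool), method="patch")
        with pytest.raises(ValueError):
            white_normalize(image, patch)


class TestDelineate:
    def test_ms_rectangle_encloses_exact_pixel_centers(self):
        image = np.ones((10, 10, 3))
        poly = [(1.5, 1.5), (1.5, 7.5), (6.5, 7.5), (6.5, 1.5)]
        region = delineate_sclera(image, "MS", manual_polygon=poly)
        expected = np.zeros((10, 10), dtype=bool)
        expected[2:7, 2:8] = True
        assert np.array_equal(region.mask, expected)
        assert region.method == "MS"

    def test_ms_requires_polygon(self):
        with pytest.raises(ValueError):
            delineate_sclera(np.ones((5, 5, 3)), "MS")

    def test_polygon_needs_three_vertices(self):
        with pytest.raises(ValueError):
            polygon_mask((5, 5), [(0, 0), (4, 4)])

    def test_seeded_modes_require_seeds(self):
        with pytest.raises(ValueError):
            delineate_sclera(np.ones((5, 5, 3)), "FS")

    def test_unknown_mode_rejected(self):
        seeds = SeedPoints((0, 0), (1, 1))
        with pytest.raises(ValueError):
            delineate_sclera(np.ones((5, 5, 3)), "XX", seeds=seeds)


class TestBlueFraction:
    @pytest.mark.parametrize(
        "pixel,expected",
        [((1, 1, 1), 100 / 3), ((0, 0, 1), 100.0), ((0.2, 0.3, 0.5), 50.0)],
    )
    def test_known_pixels(self, pixel, expected):
        image = np.array([[pixel]], dtype=float)
        mask = RegionMask(mask=np.array([[True]]), method="MS")
        values, n_excluded = blue_fraction_map(image, mask)
        assert values == pytest.approx([expected])
        assert n_excluded == 0

    def test_zero_sum_pixels_excluded_and_counted(self):
        image = np.array([[[1, 1, 1], [0, 0, 0], [0, 0, 2]]], dtype=float)
        mask = RegionMask(mask=np.ones((1, 3), bool), method="MS")
        values, n_excluded = blue_fraction_map(image, mask)
        assert sorted(values) == pytest.approx([100 / 3, 100.0])
        assert n_excluded == 1

    def test_all_zero_sum_rejected(self):
        image = np.zeros((2, 2, 3))
        mask = RegionMask(mask=np.ones((2, 2), bool), method="MS")
        with pytest.raises(ValueError):
            blue_fraction_map(image, mask)


class TestBluePercentile:
    def test_hand_sorted_interpolation(self):
        assert blue_percentile([30, 32, 28, 34], q=75) == pytest.approx(32.5)

    def test_constant_distribution_any_q(self):
        for q in (0, 25, 50, 75, 100):
            assert blue_percentile([7.0] * 5, q=q) == pytest.approx(7.0)

    def test_uniform_draws_near_q(self, rng):
        values = rng.uniform(0, 100, size=10_000)
        assert blue_percentile(values, q=75) == pytest.approx(75.0, abs=1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            blue_percentile([])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30),
           st.integers(0, 20))
    def test_monotone_in_every_input(self, values, idx):
        before = blue_percentile(values, q=75)
        bumped = list(values)
        bumped[idx % len(bumped)] += 5.0
        assert blue_percentile(bumped, q=75) >= before

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=50),
           st.sampled_from([0, 25, 50, 75, 100]))
    def test_matches_sort_based_oracle(self, values, q):
        assert blue_percentile(values, q=q) == pytest.approx(
            percentile_oracle(values, q), abs=1e-9)


class TestComputeBp:
    def test_stage_errors_are_labeled(self):
        frames = np.full((1, 4, 4, 3), 0.5)
        stack = ExposureStack(frames=frames, exposure_times=np.array([1.0]))
        with pytest.raises(PipelineStageError, match=r"\[delineate\]"):
            compute_bp(stack, mode="MS", patch_seed=(0, 0))

    def test_same_scene_scored_twice_is_identical(self, default_scene):
        _, stack, _, seeds = default_scene
        kwargs = dict(mode="FS", patch_seed=seeds.white_seed,
                      sclera_seed=seeds.sclera_seed)
        assert compute_bp(stack, **kwargs) == compute_bp(stack, **kwargs)

    def test_result_reports_method_and_quartiles(self, default_scene):
        _, stack, _, seeds = default_scene
        res = compute_bp(stack, mode="SAS", patch_seed=seeds.white_seed,
                         sclera_seed=seeds.sclera_seed)
        assert res.method == "SAS"
        assert res.q25 <= res.q50 <= res.q75
        assert res.bp == pytest.approx(res.q75)
        assert 0 <= res.bp <= 100
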