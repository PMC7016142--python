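"""Droplet segmentation and intensity-statistic unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condensate_metrics.imaging import (
    DegenerateImageError,
    EmptyMaskError,
    FluorescenceImage,
    ROISpec,
    UndefinedStatisticError,
    index_of_dispersion,
    partition_coefficient,
    segment_droplets,
    threshold_default,
    tile_rois,
)
from condensate_metrics.synthetic import DropletImageParams, gen_droplet_image

from _oracles import intermeans_threshold_pixels, region_stats


class TestThresholdDefault:
    def test_two_population_image_separates_levels(self):
        rng = np.random.default_rng(0)
        pixels = np.full(1024, 10.0)
        pixels[512:] = 200.0
        rng.shuffle(pixels)
        pixels = pixels.reshape(32, 32)
        thr, mask = threshold_default(pixels)
        assert 10.0 < thr < 200.0
        assert np.array_equal(mask, pixels == 200.0)
        # histogram threshold agrees with the exact pixel-space fixed point
        # up to one bin width
        exact = intermeans_threshold_pixels(pixels)
        assert abs(thr - exact) <= (200 - 10) / 256

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            threshold_default(np.full((8, 8), 3.0))

    def test_recovers_ground_truth_mask_on_noiseless_two_level_image(self):
        params = DropletImageParams(
            n_droplets=4, psf_sigma_px=0.0, noise_model="none", seed=5
        )
        image, truth_mask, _ = gen_droplet_image(params)
        _, mask = threshold_default(image)
        assert np.array_equal(mask, truth_mask)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        pixels = rng.gamma(2.0, 30.0, size=(64, 64))
        _, mask1 = threshold_default(pixels)
        _, mask2 = threshold_default(4.0 * pixels + 17.0)
        assert np.array_equal(mask1, mask2)


class TestSegmentDroplets:
    def test_empty_mask_yields_empty_set(self):
        ds = segment_droplets(np.zeros((16, 16), dtype=bool))
        assert ds.n_droplets == 0
        assert ds.label_map.max() == 0

    def test_single_disk_is_one_highly_circular_region(self, disk_mask):
        mask = disk_mask(10)
        ds = segment_droplets(mask, min_area_px=4, circularity_range=(0.1, 1.0))
        assert ds.n_droplets == 1
        assert ds.table.circularity.iloc[0] > 0.8
        oracle = region_stats(mask, 4, (0.1, 1.0))
        assert ds.table.area_px.iloc[0] == oracle[0]["area"]
        assert ds.table.perimeter_px.iloc[0] == pytest.approx(oracle[0]["perimeter"])

    def test_line_plus_disk_matches_oracle_filtering(self, disk_mask):
        mask = np.zeros((40, 80), dtype=bool)
        mask[5, 10:40] = True  # 1-px-wide, 30-px line
        disk = disk_mask(10, size=27)
        mask[12:39, 50:77] |= disk
        ds = segment_droplets(mask, min_area_px=4, circularity_range=(0.1, 1.0))
        oracle = region_stats(mask, 4, (0.1, 1.0))
        assert ds.n_droplets == len(oracle)
        got = ds.table.sort_values(["centroid_y", "centroid_x"])
        for row, ref in zip(got.itertuples(), oracle):
            assert row.area_px == ref["area"]
            assert row.perimeter_px == pytest.approx(ref["perimeter"])
            assert row.circularity == pytest.approx(ref["circularity"])

    def test_labels_are_contiguous_after_filtering(self):
        rng = np.random.default_rng(11)
        mask = rng.random((32, 32)) < 0.35
        ds = segment_droplets(mask, min_area_px=3, circularity_range=(0.2, 1.0))
        labels = np.unique(ds.label_map)
        assert list(labels) == list(range(ds.n_droplets + 1))

    @pytest.mark.parametrize("radius", [5, 10, 20, 40])
    def test_disk_circularity_stays_near_one_at_all_radii(self, disk_mask, radius):
        # the weighted boundary estimator overestimates circle perimeters by
        # ~4% asymptotically, so circularity settles near 0.92 rather than
        # rising to 1; it must stay high and far above elongated shapes
        ds = segment_droplets(disk_mask(radius), min_area_px=1, circularity_range=(0.0, 1.0))
        circ = ds.table.circularity.iloc[0]
        assert circ > 0.9
        line = np.zeros((9, 40), dtype=bool)
        line[4, 2:38] = True
        line_circ = segment_droplets(line, 1, (0.0, 1.0)).table.circularity.iloc[0]
        assert circ > line_circ + 0.3

    def test_random_masks_match_flood_fill_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            mask = rng.random((16, 16)) < rng.uniform(0.2, 0.6)
            ds = segment_droplets(mask, min_area_px=1, circularity_range=(0.0, 1.0))
            oracle = region_stats(mask, 1, (0.0, 1.0))
            assert ds.n_droplets == len(oracle)
            got = ds.table.sort_values(["centroid_y", "centroid_x"])
            for row, ref in zip(got.itertuples(), oracle):
                assert row.area_px == ref["area"]
                assert row.perimeter_px == pytest.approx(ref["perimeter"], abs=1e-9)


class TestIndexOfDispersion:
    def test_constant_roi_is_zero(self):
        assert index_of_dispersion(np.full(50, 7.0)) == 0.0

    def test_hand_computed_example(self):
        # {0, 2}: sample variance 2, mean 1
        assert index_of_dispersion([0.0, 2.0]) == pytest.approx(2.0)

    def test_undefined_for_nonpositive_mean(self):
        with pytest.raises(UndefinedStatisticError):
            index_of_dispersion([0.0, 0.0])
        with pytest.raises(UndefinedStatisticError):
            index_of_dispersion([1.0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.1, 1e3), min_size=2, max_size=40),
        st.floats(0.01, 100.0),
    )
    def test_scaling_intensities_scales_iod_linearly(self, values, c):
        base = index_of_dispersion(values)
        scaled = index_of_dispersion(np.asarray(values) * c)
        assert scaled == pytest.approx(c * base, rel=1e-9)

    def test_adding_droplets_increases_iod(self):
        rng = np.random.default_rng(2)
        flat = rng.poisson(50.0, size=(64, 64)).astype(float)
        withdrop = flat.copy()
        yy, xx = np.mgrid[0:64, 0:64]
        withdrop[(yy - 32) ** 2 + (xx - 32) ** 2 <= 100] *= 10
        assert index_of_dispersion(withdrop) > index_of_dispersion(flat)


class TestTileRois:
    def test_standard_roi_geometry_rounds_to_128_px(self):
        assert ROISpec(side_um=61.63, pixel_size_nm=481.5).side_px == 128
        assert ROISpec(side_um=20.54, pixel_size_nm=160.5).side_px == 128

    @pytest.mark.parametrize("size,expected", [(256, 4), (300, 4), (128, 1)])
    def test_tile_counts_with_edge_discard(self, size, expected):
        spec = ROISpec(side_um=61.63, pixel_size_nm=481.5)
        tiles = tile_rois(np.zeros((size, size)), spec)
        assert len(tiles) == expected
        for block, _ in tiles:
            assert block.shape == (128, 128)

    def test_image_smaller_than_one_roi_raises(self):
        spec = ROISpec(side_um=61.63, pixel_size_nm=481.5)
        with pytest.raises(ValueError):
            tile_rois(np.zeros((100, 100)), spec)

    def test_offsets_are_row_major_and_disjoint(self):
        spec = ROISpec(side_um=61.63, pixel_size_nm=481.5)
        tiles = tile_rois(np.zeros((256, 300)), spec)
        offsets = [off for _, off in tiles]
        assert offsets == [(0, 0), (0, 128), (128, 0), (128, 128)]


class TestPartitionCoefficient:
    def test_uniform_image_gives_one(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:10, 5:10] = True
        value, inside, outside = partition_coefficient(np.full((20, 20), 42.0), mask)
        assert value == pytest.approx(1.0)
        assert inside == outside == pytest.approx(42.0)

    def test_two_level_image_by_construction(self):
        img = np.full((30, 30), 10.0)
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:20, 10:20] = True
        img[mask] = 100.0
        value, _, _ = partition_coefficient(img, mask)
        assert value == pytest.approx(10.0)

    def test_ground_truth_mask_recovers_partition_true_exactly(self):
        params = DropletImageParams(
            n_droplets=3, partition_true=7.0, psf_sigma_px=0.0,
            noise_model="none", seed=21,
        )
        image, mask, _ = gen_droplet_image(params)
        value, _, _ = partition_coefficient(image, mask)
        assert value == pytest.approx(7.0, abs=1e-12)

    def test_empty_and_full_masks_raise(self):
        img = np.ones((8, 8))
        with pytest.raises(EmptyMaskError):
            partition_coefficient(img, np.zeros((8, 8), dtype=bool))
        with pytest.raises(EmptyMaskError):
            partition_coefficient(img, np.ones((8, 8), dtype=bool))
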