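"""Segmentation and median-size-adjusted counting, against brute-force and
geometric oracles."""

import dataclasses
import math

import numpy as np
import pytest

from conftest import flood_fill_components
from fusagg import imgsim, segquant
from fusagg.segquant import (
    Frame,
    MedianCalibration,
    calibrate_medians,
    detect_aggregates,
    estimate_background,
    quantify_frame,
    segment_cells,
    segment_frame,
    transfection_efficiency,
)


def _disk(img, cy, cx, r, value):
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    img[np.hypot(yy - cy, xx - cx) <= r] = value
    return img


class TestEstimateBackground:
    def test_constant_frame_degenerate(self):
        bg = estimate_background(Frame(np.full((32, 32), 10.0)))
        assert (bg.mean, bg.sd) == (10.0, 0.0)
        assert bg.degenerate

    def test_gaussian_background_unbiased(self):
        rng = np.random.default_rng(0)
        frame = Frame(np.clip(rng.normal(10, 2, (256, 256)), 0, None))
        bg = estimate_background(frame)
        assert abs(bg.mean - 10.0) < 0.1
        assert abs(bg.sd - 2.0) < 0.15

    def test_saturated_tail_excluded(self):
        """1% saturated pixels do not shift the background estimate."""
        rng = np.random.default_rng(1)
        clean = np.clip(rng.normal(10, 2, (200, 200)), 0, None)
        dirty = clean.copy()
        idx = rng.choice(clean.size, size=clean.size // 100, replace=False)
        dirty.ravel()[idx] = 4000.0
        bg_clean = estimate_background(Frame(clean))
        bg_dirty = estimate_background(Frame(dirty))
        assert abs(bg_dirty.mean - bg_clean.mean) < 0.1


class TestSegmentCells:
    def test_pure_background_empty_mask(self):
        rng = np.random.default_rng(2)
        frame = Frame(np.clip(rng.normal(5, 1, (64, 64)), 0, None))
        bg = estimate_background(frame)
        mask, areas = segment_cells(frame, bg.mean, bg.sd)
        assert not mask.any() and areas == []

    def test_disk_area_matches_geometry(self, small_config):
        """One rendered disk of radius 8: one component whose area is the
        disk area pi*8^2 within 15%."""
        cfg = dataclasses.replace(small_config, n_cells=1, cell_radius_px=(8.0, 0.0))
        frame, truth = imgsim.generate_frame(cfg, seed=4)
        seg = segment_frame(frame)
        assert len(seg.cell_components) == 1
        assert seg.cell_components[0] == pytest.approx(math.pi * 64, rel=0.15)

    def test_two_disks_disjoint_then_merged(self):
        img = np.full((64, 64), 1.0)
        _disk(img, 16, 16, 6, 50.0)
        _disk(img, 16, 40, 6, 50.0)
        mask, areas = segment_cells(Frame(img), 1.0, 0.5)
        assert len(areas) == 2
        img2 = np.full((64, 64), 1.0)
        _disk(img2, 16, 26, 6, 50.0)
        _disk(img2, 16, 32, 6, 50.0)
        _, areas2 = segment_cells(Frame(img2), 1.0, 0.5)
        assert len(areas2) == 1

    def test_degenerate_background_fallback(self):
        img = np.full((32, 32), 4.0)
        _disk(img, 16, 16, 6, 50.0)
        mask, areas = segment_cells(Frame(img), 4.0, 0.0, fallback_factor=1.5)
        assert len(areas) == 1  # threshold 6.0 from the fallback

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_components_match_flood_fill_oracle(self, seed):
        """On small frames the mask and component areas equal a brute-force
        flood-fill labelling exactly."""
        rng = np.random.default_rng(seed)
        img = np.where(rng.random((48, 48)) < 0.35, 50.0, 1.0)
        frame = Frame(img)
        mask, areas = segment_cells(frame, 1.0, 1.0, k_cell=3.0, min_cell_area_px=3)
        oracle = [c for c in flood_fill_components(img > 4.0) if len(c) >= 3]
        assert sorted(areas) == sorted(len(c) for c in oracle)
        oracle_mask = np.zeros_like(mask)
        for comp in oracle:
            for i, j in comp:
                oracle_mask[i, j] = True
        np.testing.assert_array_equal(mask, oracle_mask)


class TestDetectAggregates:
    def test_uniform_cell_has_no_aggregates(self):
        img = np.full((32, 32), 1.0)
        img[8:24, 8:24] = 100.0
        mask = img > 50
        agg_mask, areas, thr, m, s = detect_aggregates(Frame(img), mask)
        assert not agg_mask.any() and areas == []
        assert s == 0.0

    def test_empty_cell_mask_warns(self):
        with pytest.warns(UserWarning, match="empty cell mask"):
            agg_mask, areas, *_ = detect_aggregates(
                Frame(np.ones((16, 16))), np.zeros((16, 16), bool)
            )
        assert not agg_mask.any()

    def test_injected_focus_recovered_exactly(self):
        """A 5-pixel focus at ~25 cell-SDs above the cell mean is recovered
        as exactly that component at the default 18-SD threshold."""
        img = np.full((80, 80), 1.0)
        cell = np.zeros((80, 80), bool)
        cell[5:75, 5:75] = True
        ripple = np.indices((80, 80)).sum(axis=0) % 2  # checkerboard, SD ~0.5
        img[cell] = 100.0 + ripple[cell]
        focus = [(40, 40), (39, 40), (41, 40), (40, 39), (40, 41)]
        base_sd = img[cell].std()
        for i, j in focus:
            img[i, j] = 100.0 + 25.0 * base_sd
        agg_mask, areas, thr, m, s = detect_aggregates(Frame(img), cell)
        assert areas == [5]
        assert {tuple(p) for p in np.argwhere(agg_mask)} == set(focus)

    def test_raising_k_sigma_never_grows_area(self):
        cfg = imgsim.GeneratorConfig(
            frame_shape=(200, 200), n_cells=3, cell_radius_px=(20.0, 1.0),
            aggregates_per_cell_lambda=2.0, aggregate_intensity_multiplier=50.0,
        )
        frame, _ = imgsim.generate_frame(cfg, seed=6)
        seg = segment_frame(frame)
        prev = np.inf
        for k in (2.0, 6.0, 12.0, 18.0, 30.0):
            _, areas, *_ = detect_aggregates(frame, seg.cell_mask, k_sigma=k)
            total = sum(areas)
            assert total <= prev
            prev = total

    def test_aggregate_mask_subset_of_cell_mask(self, small_config):
        cfg = dataclasses.replace(
            small_config, aggregates_per_cell_lambda=1.5,
            aggregate_intensity_multiplier=100.0,
        )
        frame, _ = imgsim.generate_frame(cfg, seed=8)
        seg = segment_frame(frame)
        assert not np.any(seg.aggregate_mask & ~seg.cell_mask)


class TestMedianCalibration:
    def _seg(self, cell_areas, agg_areas):
        empty = np.zeros((4, 4), bool)
        return segquant.SegmentationResult(
            background_mean=0.0, background_sd=1.0, cell_mask=empty,
            aggregate_mask=empty, cell_components=cell_areas,
            aggregate_components=agg_areas, cell_pixel_mean=0.0,
            cell_pixel_sd=0.0, threshold_used=0.0, k_sigma=18.0,
            cell_intensity_sum=0.0,
        )

    def test_odd_and_even_medians(self):
        calib = calibrate_medians([self._seg([90, 100, 110], [])])
        assert calib.median_cell_area == 100
        calib = calibrate_medians([self._seg([80, 120], [])])
        assert calib.median_cell_area == 100  # midpoint convention

    def test_permutation_invariance(self):
        segs = [self._seg([10 * i + 10], [i + 1]) for i in range(7)]
        assert calibrate_medians(segs) == calibrate_medians(segs[::-1])

    def test_no_cells_is_an_error(self):
        with pytest.raises(ValueError):
            calibrate_medians([self._seg([], [])])


class TestQuantifyFrame:
    def _seg_with_masks(self, img, cell_mask, agg_mask, cell_areas, agg_areas):
        return segquant.SegmentationResult(
            background_mean=0.0, background_sd=1.0, cell_mask=cell_mask,
            aggregate_mask=agg_mask, cell_components=cell_areas,
            aggregate_components=agg_areas, cell_pixel_mean=0.0, cell_pixel_sd=0.0,
            threshold_used=10.0, k_sigma=18.0,
            cell_intensity_sum=float(img[cell_mask].sum()),
        )

    def test_count_arithmetic(self):
        img = np.ones((40, 40))
        cell_mask = np.zeros((40, 40), bool)
        cell_mask[:25, :40] = True  # 1000 px
        seg = self._seg_with_masks(img, cell_mask, np.zeros((40, 40), bool), [1000], [])
        calib = MedianCalibration(100.0, 5.0, 1)
        q = quantify_frame(seg, calib)
        assert q.cell_count == pytest.approx(10.0)
        assert q.aggregate_count == 0.0 and q.aggregates_per_cell == 0.0

    def test_no_cells_reports_missing(self):
        empty = np.zeros((8, 8), bool)
        seg = self._seg_with_masks(np.ones((8, 8)), empty, empty, [], [])
        q = quantify_frame(seg, MedianCalibration(100.0, None, 1))
        assert math.isnan(q.aggregates_per_cell)
        assert math.isnan(q.fluorescence_per_cell)

    def test_duplicating_components_doubles_counts(self):
        """Scale consistency: a frame containing every component twice has
        twice the areas and twice the counts under a fixed calibration."""
        rng = np.random.default_rng(3)
        tile = np.clip(rng.normal(2, 0.5, (80, 80)), 0, None)
        _disk(tile, 20, 20, 7, 80.0)
        _disk(tile, 55, 50, 9, 60.0)
        single = Frame(tile)
        double = Frame(np.hstack([tile, tile]))
        calib = MedianCalibration(150.0, 4.0, 1)
        q1 = quantify_frame(segment_frame(single), calib)
        q2 = quantify_frame(segment_frame(double), calib)
        assert q2.total_cell_area == pytest.approx(2 * q1.total_cell_area, rel=0.02)
        assert q2.cell_count == pytest.approx(2 * q1.cell_count, rel=0.02)


class TestTransfectionEfficiency:
    def test_exact_fraction(self, small_config):
        cfg = dataclasses.replace(
            small_config, frame_shape=(300, 300), n_cells=25, transfected_fraction=0.6
        )
        frame, truth = imgsim.generate_frame(cfg, seed=10)
        frac = transfection_efficiency([frame], [truth.n_cells])
        assert frac == pytest.approx(truth.n_transfected / truth.n_cells)

    def test_zero_fluorescing(self, small_config):
        cfg = dataclasses.replace(small_config, transfected_fraction=0.0)
        frame, truth = imgsim.generate_frame(cfg, seed=11)
        assert transfection_efficiency([frame], [truth.n_cells]) == 0.0

    def test_missing_totals_rejected(self, small_config):
        frame, _ = imgsim.generate_frame(small_config, seed=12)
        with pytest.raises(ValueError):
            transfection_efficiency([frame], [])
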