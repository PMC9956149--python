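"""Generator contracts: determinism, conservation, distributional means."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fusagg import imgsim
from fusagg.imgsim import GeneratorConfig, PlacementError


class TestGenerateFrame:
    def test_empty_field_is_pure_background(self, small_config):
        cfg = dataclasses.replace(small_config, n_cells=0)
        frame, truth = imgsim.generate_frame(cfg, seed=1)
        assert truth.n_cells == 0 and truth.total_foci == 0
        assert frame.pixels.max() < cfg.background_level + 6 * cfg.background_noise_sd

    def test_same_seed_bitwise_identical(self, small_config):
        f1, _ = imgsim.generate_frame(small_config, seed=42)
        f2, _ = imgsim.generate_frame(small_config, seed=42)
        np.testing.assert_array_equal(f1.pixels, f2.pixels)

    def test_different_seeds_differ(self, small_config):
        f1, _ = imgsim.generate_frame(small_config, seed=1)
        f2, _ = imgsim.generate_frame(small_config, seed=2)
        assert not np.array_equal(f1.pixels, f2.pixels)

    def test_placement_failure_raises(self, small_config):
        cfg = dataclasses.replace(small_config, n_cells=500)  # cannot fit
        with pytest.raises(PlacementError):
            imgsim.generate_frame(cfg, seed=0)

    def test_transfected_fraction_binomial(self, small_config):
        """Ground-truth transfection flags follow the configured binomial
        rate: the grand mean over 100 seeds sits within 3 SE of 0.6."""
        cfg = dataclasses.replace(
            small_config, frame_shape=(220, 220), n_cells=30,
            cell_radius_px=(5.0, 0.5), transfected_fraction=0.6,
        )
        fracs = []
        for seed in range(100):
            _, truth = imgsim.generate_frame(cfg, seed=seed)
            assert truth.n_transfected == sum(c.transfected for c in truth.cells)
            fracs.append(truth.n_transfected / truth.n_cells)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.6) < 3 * se + 1e-12

    def test_foci_conservation_and_containment(self, small_config):
        cfg = dataclasses.replace(small_config, aggregates_per_cell_lambda=2.0)
        _, truth = imgsim.generate_frame(cfg, seed=3)
        assert truth.total_foci == sum(c.foci_count for c in truth.cells)
        for cell in truth.cells:
            assert len(cell.foci_centers) == cell.foci_count
            for fy, fx in cell.foci_centers:
                d = np.hypot(fy - cell.center[0], fx - cell.center[1])
                assert d + cfg.aggregate_radius_px <= cell.radius


class TestGenerateTimelapse:
    def test_no_rupture_keeps_all_cells(self, small_config):
        frames, truth = imgsim.generate_timelapse(
            small_config, times=[1, 2, 3, 4], rupture_rate=0.0, seed=5
        )
        assert truth.frames[0].n_cells == truth.frames[-1].n_cells
        assert truth.alive_matrix.all()
        assert not truth.ruptures

    def test_constant_rate_poisson_mean(self, small_config):
        """With λ(t) = 2 and no rupture the mean true foci count per cell
        across frames sits within 3 SE of 2 (Poisson oracle)."""
        cfg = dataclasses.replace(small_config, aggregates_per_cell_lambda=2.0)
        counts = []
        for seed in range(15):
            _, truth = imgsim.generate_timelapse(cfg, times=list(range(10)), seed=seed)
            for ft in truth.frames:
                counts.extend(c.foci_count for c in ft.cells)
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 2.0) < 3 * se

    def test_rupture_log_matches_alive_matrix(self, small_config):
        """Logged rupture events replay exactly as the per-frame survival
        record: one event per alive→dead transition, at that frame's time."""
        frames, truth = imgsim.generate_timelapse(
            small_config, times=list(range(20)), rupture_rate=0.2, seed=9
        )
        assert truth.ruptures  # rate 0.2 over 19 transitions: certain
        transitions = []
        for i in range(1, truth.alive_matrix.shape[0]):
            for j in np.nonzero(truth.alive_matrix[i - 1] & ~truth.alive_matrix[i])[0]:
                transitions.append((int(j), float(i)))
        logged = [(r.cell_index, r.time_h) for r in truth.ruptures]
        assert sorted(logged) == sorted(transitions)
        # dead cells take their foci with them
        for i, ft in enumerate(truth.frames):
            assert ft.n_cells == int(truth.alive_matrix[i].sum())

    def test_times_validation(self, small_config):
        with pytest.raises(ValueError):
            imgsim.generate_timelapse(small_config, times=[], seed=0)
        with pytest.raises(ValueError):
            imgsim.generate_timelapse(small_config, times=[2, 1], seed=0)


class TestCountTable:
    @pytest.fixture
    def means(self):
        return pd.DataFrame(
            {
                "transcript_id": ["a", "b", "c"],
                "mapping_class": ["unique", "multi", "unique"],
                "family": ["A", "B", "C"],
                "x": [0.0, 5.0, 40.0],
                "y": [3.0, 5.0, 80.0],
            }
        )

    def test_zero_mean_gives_zero_counts(self, means):
        table = imgsim.generate_count_table(means, n_replicates=4, seed=0)
        assert (table.filter(like="x_").loc[table.transcript_id == "a"] == 0).all().all()

    def test_negative_mean_rejected(self, means):
        means.loc[0, "x"] = -1.0
        with pytest.raises(ValueError):
            imgsim.generate_count_table(means, seed=0)

    def test_determinism_and_poisson_mean(self, means):
        t1 = imgsim.generate_count_table(means, seed=7)
        t2 = imgsim.generate_count_table(means, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        draws = [
            imgsim.generate_count_table(means, seed=s).loc[2, ["y_1", "y_2", "y_3"]]
            for s in range(100)
        ]
        arr = np.concatenate([d.to_numpy(dtype=float) for d in draws])
        se = arr.std(ddof=1) / np.sqrt(arr.size)
        assert abs(arr.mean() - 80.0) < 3 * se


class TestToxicityPlate:
    def test_ratio_zero_gives_zero_pre(self):
        plate = imgsim.generate_toxicity_plate({"a": 0.0}, seed=1)
        assert (plate["pre_lysis"] == 0).all()

    def test_ratio_one_gives_pre_near_post(self):
        plate = imgsim.generate_toxicity_plate({"a": 1.0}, noise_sigma_log=0.01, seed=1)
        np.testing.assert_allclose(plate["pre_lysis"], plate["post_lysis"], rtol=0.05)

    def test_determinism(self):
        p1 = imgsim.generate_toxicity_plate({"a": 0.3, "b": 0.5}, seed=3)
        p2 = imgsim.generate_toxicity_plate({"a": 0.3, "b": 0.5}, seed=3)
        pd.testing.assert_frame_equal(p1, p2)


class TestLaneProfile:
    def test_fraction_zero_is_single_peak(self):
        profile, truth = imgsim.generate_lane_profile(0.0, noise_sd=0.0, seed=0)
        assert truth.smear_area == 0
        # all signal (above the offset) lies near the monomer position
        above = profile.positions[profile.signal > profile.signal.max() * 0.05]
        assert above.min() > 50.0

    def test_fraction_half_splits_areas_equally(self):
        _, truth = imgsim.generate_lane_profile(0.5, seed=0)
        assert truth.smear_area == pytest.approx(truth.monomer_area)

    def test_determinism(self):
        p1, _ = imgsim.generate_lane_profile(0.4, seed=11)
        p2, _ = imgsim.generate_lane_profile(0.4, seed=11)
        np.testing.assert_array_equal(p1.signal, p2.signal)
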