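"""End-to-end recovery pipelines over the preset scenarios.

Each ``recover_*`` function generates synthetic data for one preset, runs
the full measurement pipeline on it (never the ground truth), and returns
the recovered effect sizes next to the injected ones. These functions are
the library behind the ``run`` CLI subcommand, the acceptance script and
the validation suite.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import imgsim, kinetics, segquant, trnaseq
from .cytotox import normalize_to_control, plate_ratios
from .presets import Preset, get_preset
from .sddage import fraction_aggregated, subtract_baseline

__all__ = [
    "child_seeds",
    "run_imaging_preset",
    "run_timelapse_preset",
    "condition_means",
    "recover_fluorescence_ratios",
    "recover_transfection_efficiency",
    "recover_count_statistics",
    "recover_toxicity",
    "recover_aggregation_folds",
    "recover_plateau_ratio",
    "rupture_event_comparison",
    "recover_lane_fractions",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic stream of sub-seeds (< 2**31) from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# imaging presets
# ---------------------------------------------------------------------------

def run_imaging_preset(
    preset: str | Preset,
    seed: int,
    conditions: Sequence[str] | None = None,
    n_replicates: int | None = None,
    k_sigma: float = 18.0,
    k_cell: float = 3.0,
) -> pd.DataFrame:
    """Generate replicate frames per condition, segment them, calibrate the
    median areas over the whole experiment and quantify every frame.

    Returns the tidy per-frame quantification table.
    """
    p = get_preset(preset) if isinstance(preset, str) else preset
    conds = list(conditions) if conditions is not None else list(p.conditions)
    reps = n_replicates if n_replicates is not None else p.base_config.n_replicates
    seeds = iter(child_seeds(seed, len(conds) * reps))
    segs = []
    for cond in conds:
        cfg = p.config_for(cond)
        for rep in range(1, reps + 1):
            frame, _ = imgsim.generate_frame(
                cfg, seed=next(seeds), condition=cond, replicate=str(rep)
            )
            segs.append(segquant.segment_frame(frame, k_cell=k_cell, k_sigma=k_sigma))
    calib = segquant.calibrate_medians(segs)
    quants = [segquant.quantify_frame(s, calib) for s in segs]
    return kinetics.quant_frame_table(quants)


def condition_means(df: pd.DataFrame, metric: str) -> pd.Series:
    """Replicate-mean metric per condition."""
    return df.groupby("condition")[metric].mean()


def recover_fluorescence_ratios(
    seed: int, preset: str = "fig1", n_replicates: int | None = None
) -> dict:
    """Per-cell fluorescence ratios between conditions, recovered by the
    segmentation pipeline from synthetic replicate frames."""
    p = get_preset(preset)
    df = run_imaging_preset(p, seed, n_replicates=n_replicates)
    means = condition_means(df, "fluorescence_per_cell")
    injected = {
        cond: cspec.get("intensity_factor", 1.0) for cond, cspec in p.conditions.items()
    }
    ref = "none" if "none" in means.index else next(iter(p.conditions))
    recovered = {cond: float(means[cond] / means[ref]) for cond in means.index}
    return {"reference": ref, "recovered": recovered, "injected": injected, "quant": df}


def recover_fig5_ratios(seed: int) -> dict:
    """FUS-arm per-cell fluorescence folds (wild-type tRNA vs none and vs
    the mistranslating tRNA)."""
    p = get_preset("fig5")
    conds = ["none/FUS", "AGA/FUS", "AAA/FUS"]
    df = run_imaging_preset(p, seed, conditions=conds)
    means = condition_means(df, "fluorescence_per_cell")
    return {
        "fold_AGA_over_none": float(means["AGA/FUS"] / means["none/FUS"]),
        "fold_AGA_over_AAA": float(means["AGA/FUS"] / means["AAA/FUS"]),
        "injected": p.ground_truth,
        "quant": df,
    }


def recover_transfection_efficiency(seed: int, n_frames: int = 100) -> dict:
    """Transfection efficiency: fluorescing-cell count (segmentation) over
    ground-truth total cells, pooled across independently seeded frames."""
    p = get_preset("transfection")
    cfg = p.config_for("default")
    fractions = []
    fluorescing_total = 0
    cells_total = 0
    for s in child_seeds(seed, n_frames):
        frame, truth = imgsim.generate_frame(cfg, seed=s)
        frac = segquant.transfection_efficiency([frame], [truth.n_cells])
        fractions.append(frac)
        fluorescing_total += round(frac * truth.n_cells)
        cells_total += truth.n_cells
    arr = np.asarray(fractions)
    return {
        "mean_fraction": float(arr.mean()),
        "se": float(arr.std(ddof=1) / math.sqrt(arr.size)),
        "pooled_fraction": fluorescing_total / cells_total,
        "n_frames": n_frames,
        "injected": p.ground_truth["transfected_fraction"],
    }


# ---------------------------------------------------------------------------
# time-lapse presets
# ---------------------------------------------------------------------------

def run_timelapse_preset(
    preset: str | Preset,
    seed: int,
    conditions: Sequence[str] | None = None,
    n_replicates: int | None = None,
    k_sigma: float = 18.0,
    config_overrides: dict | None = None,
) -> pd.DataFrame:
    """Generate per-condition replicate time-lapses, segment every frame,
    calibrate medians over the entire experiment (all conditions and times)
    and quantify. Returns the tidy quantification table."""
    p = get_preset(preset) if isinstance(preset, str) else preset
    if p.times is None:
        raise ValueError(f"preset {p.name!r} is not a time-lapse preset")
    conds = list(conditions) if conditions is not None else list(p.conditions)
    reps = n_replicates if n_replicates is not None else p.base_config.n_replicates
    seeds = iter(child_seeds(seed, len(conds) * reps))
    segs = []
    for cond in conds:
        cfg = p.config_for(cond, **(config_overrides or {}))
        lam = p.trajectory_for(cond)
        for rep in range(1, reps + 1):
            frames, _ = imgsim.generate_timelapse(
                cfg, p.times, trajectory=lam, seed=next(seeds),
                condition=cond, replicate=str(rep),
            )
            segs.extend(segquant.segment_frame(f, k_sigma=k_sigma) for f in frames)
    calib = segquant.calibrate_medians(segs)
    quants = [segquant.quantify_frame(s, calib) for s in segs]
    return kinetics.quant_frame_table(quants)


def recover_aggregation_folds(seed: int, preset: str = "fig6-FUS") -> dict:
    """Aggregates-per-cell fold (wild-type tRNA vs none) at the first and
    last time points of the wild-type FUS time course."""
    p = get_preset(preset)
    df = run_timelapse_preset(p, seed, conditions=["none", "AGA"])
    t0, t1 = p.times[0], p.times[-1]
    return {
        "fold_start": kinetics.fold_change_at(df, "AGA", "none", t0),
        "fold_end": kinetics.fold_change_at(df, "AGA", "none", t1),
        "injected_start": p.ground_truth["fold_AGA_over_none_start"],
        "injected_end": p.ground_truth["fold_AGA_over_none_end"],
        "quant": df,
    }


def recover_plateau_ratio(seed: int, window_h: float = 5.0) -> dict:
    """Plateau-level aggregates-per-cell ratio (mistranslating tRNA vs none)
    for the aggregation-prone FUS variant."""
    p = get_preset("fig6-R521C")
    df = run_timelapse_preset(p, seed, conditions=["none", "AAA"])
    lvl_aaa, _, _ = kinetics.plateau_level(df, "AAA", window_h=window_h)
    lvl_none, _, _ = kinetics.plateau_level(df, "none", window_h=window_h)
    return {
        "plateau_ratio": lvl_aaa / lvl_none,
        "injected": p.ground_truth["plateau_fold_AAA_over_none"],
        "quant": df,
    }


#: Field scale used for the paired rupture-detection comparison: a small
#: field of view where losing one cell is a visible fraction of the total
#: fluorescence. min_drop is matched to that single-cell loss fraction.
RUPTURE_FIELD = {"frame_shape": (750, 750), "n_cells": 20}
RUPTURE_MIN_DROP = 0.04


def rupture_event_comparison(seed: int, n_pairs: int = 50) -> dict:
    """Paired-seed comparison of detected sudden-drop events in the
    mistranslating-tRNA course of the mutant-FUS preset, with the preset's
    rupture rate versus a rupture-free control run of the same seed.

    Detection runs on total cell-mask fluorescence of small fields
    (aggregates-per-cell is per-cell-normalized and thus insensitive to
    whole-cell loss at population scale)."""
    p = get_preset("fig6-R521C")
    lam = p.trajectory_for("AAA")
    rate = p.conditions["AAA"]["rupture_rate"]
    cfg = p.config_for("AAA", **RUPTURE_FIELD)
    more = 0
    counts = []
    for s in child_seeds(seed, n_pairs):
        events = {}
        for label, r in (("ruptures", rate), ("control", 0.0)):
            frames, _ = imgsim.generate_timelapse(
                cfg, p.times, trajectory=lam, rupture_rate=r, seed=s,
                condition="AAA", replicate="1",
            )
            segs = [segquant.segment_frame(f) for f in frames]
            calib = segquant.calibrate_medians(segs)
            quants = [segquant.quantify_frame(sg, calib) for sg in segs]
            df = kinetics.quant_frame_table(quants)
            tc = kinetics.TimeCourse(
                "AAA", "1", df["time_h"].to_numpy(), df["total_fluorescence"].to_numpy()
            )
            events[label] = len(
                kinetics.detect_ruptures(tc, min_drop=RUPTURE_MIN_DROP, metric="total_fluorescence")
            )
        counts.append((events["ruptures"], events["control"]))
        if events["ruptures"] > events["control"]:
            more += 1
    return {"n_pairs": n_pairs, "pairs_with_more": more, "fraction_more": more / n_pairs, "counts": counts}


# ---------------------------------------------------------------------------
# counts, toxicity, lanes
# ---------------------------------------------------------------------------

def recover_count_statistics(seed: int, n_tables: int = 200) -> dict:
    """tRNA-seq recoveries over independently seeded count tables: the mean
    mutant-transcript read count in mutant-expressing samples, the pooled
    wild-type isodecoder pool size, and the injected Lys-TTT fold change."""
    p = get_preset("fig2")
    means_spec = p.payload["count_means"]
    reps = p.payload["n_replicates"]
    mutant_means = []
    pool_means = []
    lys_folds = []
    for s in child_seeds(seed, n_tables):
        table = imgsim.generate_count_table(means_spec, n_replicates=reps, seed=s)
        aaa_cols = trnaseq.condition_columns(table, "AAA")
        row = table.loc[table["transcript_id"] == "Ser-AAA-2-3", aaa_cols]
        mutant_means.append(float(row.to_numpy().mean()))
        pooled = trnaseq.pool_counts(table)
        pool_row = pooled.loc[pooled["transcript_id"] == "Ser-AGA", trnaseq.sample_columns(pooled)]
        pool_means.append(float(pool_row.to_numpy().mean()))
        results = trnaseq.differential_abundance(table, "AAA", "AGA")
        lys = next(r for r in results if r.transcript_id == "Lys-TTT-1-1")
        lys_folds.append(lys.fold_change)
    # pool fractions of the mutant transcript, from the last pooled table
    ser_pool_ids = ["Ser-AGA", "Ser-GCT", "Ser-CGA", "Ser-TGA-1-1"]
    fractions = trnaseq.pool_fractions(
        pooled, "Ser-AAA-2-3", ser_pool_ids, "Ser-AGA", ["Phe-GAA"],
        condition="AAA", transfection_efficiency=0.60,
    )
    return {
        "mutant_mean": float(np.mean(mutant_means)),
        "mutant_se": float(np.std(mutant_means, ddof=1) / math.sqrt(n_tables)),
        "pool_mean": float(np.mean(pool_means)),
        "pool_se": float(np.std(pool_means, ddof=1) / math.sqrt(n_tables)),
        "lys_fold": float(np.mean(lys_folds)),
        "pool_fractions": {
            "of_ser_pool": fractions.fraction_of_ser_pool,
            "of_aga_pool": fractions.fraction_of_aga_pool,
            "of_phe_decoders": fractions.fraction_of_phe_decoders,
            "transfection_adjusted": fractions.transfection_adjusted_fraction,
        },
        "injected": p.ground_truth,
        "n_tables": n_tables,
    }


def recover_toxicity(seed: int, n_plates: int = 200) -> dict:
    """Normalized dead/total ratios per condition, averaged over seeded
    plates, plus the headline mutant-tRNA + mutant-FUS vs no-tRNA +
    wild-type-FUS comparison."""
    p = get_preset("fig4")
    pl = p.payload
    per_condition: dict[str, list[float]] = {}
    for s in child_seeds(seed, n_plates):
        plate = imgsim.generate_toxicity_plate(
            pl["death_ratios"], post_lysis_mean=pl["post_lysis_mean"],
            noise_sigma_log=pl["noise_sigma_log"], n_replicates=pl["n_replicates"], seed=s,
        )
        summary = normalize_to_control(plate_ratios(plate), control=pl["control"])
        for row in summary.itertuples():
            per_condition.setdefault(row.condition, []).append(row.normalized_mean)
    normalized = {c: float(np.mean(v)) for c, v in per_condition.items()}
    headline = normalized["AAA/R521C"] / normalized["none/FUS"]
    return {
        "normalized": normalized,
        "pct_higher_AAA_R521C_vs_none_FUS": 100.0 * (headline - 1.0),
        "injected": p.ground_truth,
        "n_plates": n_plates,
    }


def recover_lane_fractions(seed: int, n_seeds: int = 100) -> dict:
    """Aggregated fractions from synthetic SDD-AGE lanes (baseline
    subtraction + automatic monomer window), averaged over seeds, plus the
    wild-type FUS fold reduction and the mutant-FUS aggregated-signal ratio."""
    p = get_preset("fig7")
    fractions_spec = p.payload["fractions"]
    total_area = p.payload["total_area"]
    frac_acc: dict[str, list[float]] = {c: [] for c in fractions_spec}
    signal_acc: dict[str, list[float]] = {c: [] for c in fractions_spec}
    for s in child_seeds(seed, n_seeds):
        lane_seeds = iter(child_seeds(s, len(fractions_spec)))
        for cond, injected in fractions_spec.items():
            profile, _ = imgsim.generate_lane_profile(
                injected, total_area=total_area, seed=next(lane_seeds), condition=cond
            )
            corrected = subtract_baseline(profile)
            frac = fraction_aggregated(corrected)
            total = float(np.trapezoid(corrected.signal, corrected.positions))
            frac_acc[cond].append(frac)
            signal_acc[cond].append(frac * total)
    fractions = {c: float(np.mean(v)) for c, v in frac_acc.items()}
    signals = {c: float(np.mean(v)) for c, v in signal_acc.items()}
    return {
        "fractions": fractions,
        "fold_reduction_FUS": fractions["AGA/FUS"] / fractions["AAA/FUS"],
        "pct_R521C_AAA_over_AGA": 100.0 * signals["AAA/R521C"] / signals["AGA/R521C"],
        "injected": p.ground_truth,
        "n_seeds": n_seeds,
    }
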