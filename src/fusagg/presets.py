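"""Named scenario presets with injected ground truth.

Each preset encodes one of the experimental scenarios the pipeline was
designed around — per-cell reporter fluorescence shifts, transfection
efficiency, tRNA read-count pools, aggregation-kinetics time courses with
and without rupture, dye-exclusion toxicity plates, and SDD-AGE lane pairs —
as generator configurations plus the injected effect sizes. Downstream code
recovers those effects from the synthetic data; the ``ground_truth`` dict of
every preset lists the value each recovery is expected to return.

Effect sizes encode the experimental system this toolkit models (relative per-cell
intensities, trajectory fold factors, normalized death ratios, aggregated
fractions, mean read counts); free parameters the study does not pin down
(cell geometry, absolute intensities, noise levels, the baseline focus rate
λ0 = 0.5 per cell) are fixed here once, with rationale in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Callable

import numpy as np
import pandas as pd

from .imgsim import GeneratorConfig

__all__ = ["Preset", "get_preset", "list_presets", "PRESETS"]

#: baseline expected foci per transfected cell for the "no additional tRNA"
#: condition of the kinetics presets; the printed effects are fold factors
#: relative to this.
LAMBDA_BASELINE = 0.5


@dataclass(frozen=True)
class Preset:
    """A named scenario: base generator configuration, per-condition
    overrides and the injected ground truth every recovery target checks."""

    name: str
    kind: str  # imaging | timelapse | counts | toxicity | lanes
    description: str
    base_config: GeneratorConfig | None = None
    conditions: dict[str, dict[str, Any]] = field(default_factory=dict)
    times: tuple[float, ...] | None = None
    payload: dict[str, Any] = field(default_factory=dict)
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def config_for(self, condition: str, **overrides: Any) -> GeneratorConfig:
        """GeneratorConfig for one condition (imaging/timelapse presets)."""
        if self.base_config is None:
            raise ValueError(f"preset {self.name!r} has no imaging configuration")
        cond_spec = self.conditions.get(condition)
        if cond_spec is None:
            raise KeyError(f"unknown condition {condition!r} for preset {self.name}")
        cfg = self.base_config
        factor = cond_spec.get("intensity_factor")
        if factor is not None:
            cfg = replace(cfg, cell_mean_intensity=cfg.cell_mean_intensity * factor)
        if "rupture_rate" in cond_spec:
            cfg = replace(cfg, rupture_rate=cond_spec["rupture_rate"])
        if "lambda" in cond_spec:
            cfg = replace(cfg, aggregates_per_cell_lambda=cond_spec["lambda"])
        if overrides:
            cfg = replace(cfg, **overrides)
        return cfg

    def trajectory_for(self, condition: str) -> Callable[[float], float]:
        """λ(t) for one condition of a time-lapse preset, as piecewise-linear
        interpolation of (time, fold) knots scaled by the λ0 baseline."""
        cond_spec = self.conditions.get(condition)
        if cond_spec is None or "lambda_knots" not in cond_spec:
            raise KeyError(f"no trajectory for condition {condition!r} of {self.name}")
        knots = cond_spec["lambda_knots"]
        ts = np.array([k[0] for k in knots], dtype=float)
        folds = np.array([k[1] for k in knots], dtype=float)

        def lam(t: float) -> float:
            return float(LAMBDA_BASELINE * np.interp(t, ts, folds))

        return lam


def _fig2_count_means() -> pd.DataFrame:
    """Per-transcript expected read counts for the tRNA-seq scenario.

    The mutant Ser-AAA-2-3 transcript maps uniquely (26 reads on average in
    mutant-expressing samples, background 0.5 in wild-type samples); the six
    identical Ser-AGA-2-x gene copies are multi-mapped and pool to ~2000
    reads; the Phe-GAA decoder pool is sized so the mutant is 1.4% of Phe
    decoders; Lys-TTT-1-1 carries an injected 1.8-fold increase in wild-type
    samples and the mitochondrial Cys tRNA a 1.5-fold one; ~30 further
    transcripts form an unchanged background pool.
    """
    rows: list[dict[str, Any]] = [
        {"transcript_id": "Ser-AAA-2-3", "mapping_class": "unique",
         "family": "Ser-AAA", "AGA": 0.5, "AAA": 26.0},
        {"transcript_id": "Lys-TTT-1-1", "mapping_class": "unique",
         "family": "Lys-TTT", "AGA": 900.0, "AAA": 500.0},
        {"transcript_id": "mt-Cys-GCA-1-1", "mapping_class": "unique",
         "family": "mt-Cys-GCA", "AGA": 300.0, "AAA": 200.0},
        {"transcript_id": "Ser-TGA-1-1", "mapping_class": "unique",
         "family": "Ser-TGA", "AGA": 1700.0, "AAA": 1700.0},
    ]
    for i in range(1, 7):  # six identical gene copies -> one multi-mapped pool
        rows.append(
            {"transcript_id": f"Ser-AGA-2-{i}", "mapping_class": "multi",
             "family": "Ser-AGA", "AGA": 2000.0 / 6, "AAA": 2000.0 / 6}
        )
    for i in range(1, 4):
        rows.append(
            {"transcript_id": f"Ser-GCT-1-{i}", "mapping_class": "multi",
             "family": "Ser-GCT", "AGA": 1000.0, "AAA": 1000.0}
        )
    for i in range(1, 3):
        rows.append(
            {"transcript_id": f"Ser-CGA-1-{i}", "mapping_class": "multi",
             "family": "Ser-CGA", "AGA": 1000.0, "AAA": 1000.0}
        )
    for i in range(1, 4):
        rows.append(
            {"transcript_id": f"Phe-GAA-1-{i}", "mapping_class": "multi",
             "family": "Phe-GAA", "AGA": 1857.0 / 3, "AAA": 1857.0 / 3}
        )
    background_families = [
        "Ala-AGC", "Arg-ACG", "Arg-TCT", "Asn-GTT", "Asp-GTC", "Cys-GCA",
        "Gln-CTG", "Glu-CTC", "Gly-GCC", "Gly-TCC", "His-GTG", "Ile-AAT",
        "Leu-CAA", "Leu-TAA", "Met-CAT", "Pro-AGG", "Pro-TGG", "Thr-AGT",
        "Trp-CCA", "Tyr-GTA", "Val-AAC", "Val-TAC", "Lys-CTT", "Phe-GAA-nc",
        "Ala-TGC", "Arg-CCT", "Asn-ATT", "Gln-TTG", "Glu-TTC", "Ile-TAT",
    ]
    for i, fam in enumerate(background_families):
        mean = 150.0 + (i * 211) % 1200  # fixed spread of abundances
        rows.append(
            {"transcript_id": f"{fam}-1-1", "mapping_class": "unique",
             "family": fam, "AGA": mean, "AAA": mean}
        )
    return pd.DataFrame(rows)


def _build_presets() -> dict[str, Preset]:
    presets: dict[str, Preset] = {}

    # -- per-cell reporter fluorescence, three tRNA conditions ------------
    presets["fig1"] = Preset(
        name="fig1",
        kind="imaging",
        description=(
            "Diffuse reporter fluorescence per cell: wild-type tRNA raises the "
            "mean per-cell intensity 33%, the mistranslating variant lowers it 22%."
        ),
        base_config=GeneratorConfig(
            frame_shape=(1000, 1000),
            n_cells=400,
            transfected_fraction=1.0,
            cell_radius_px=(12.0, 1.5),
            cell_mean_intensity=100.0,
            background_level=2.0,
            background_noise_sd=0.5,
            aggregates_per_cell_lambda=0.0,
            n_replicates=4,
        ),
        conditions={
            "none": {"intensity_factor": 1.00},
            "AGA": {"intensity_factor": 1.33},
            "AAA": {"intensity_factor": 0.78},
        },
        ground_truth={
            "intensity_ratio": {"AGA/none": 1.33, "AAA/none": 0.78},
            "percent_increase_AGA": 33.0,
            "percent_decrease_AAA": 22.0,
        },
    )

    # -- transfection efficiency ------------------------------------------
    presets["transfection"] = Preset(
        name="transfection",
        kind="imaging",
        description="60% of plated cells fluoresce (carry the reporter plasmid).",
        base_config=GeneratorConfig(
            frame_shape=(600, 600),
            n_cells=100,
            transfected_fraction=0.60,
            cell_radius_px=(12.0, 2.0),
            cell_mean_intensity=100.0,
            background_level=2.0,
            background_noise_sd=0.5,
            aggregates_per_cell_lambda=0.0,
            n_replicates=1,
        ),
        conditions={"default": {}},
        ground_truth={"transfected_fraction": 0.60},
    )

    # -- tRNA-seq count tables --------------------------------------------
    presets["fig2"] = Preset(
        name="fig2",
        kind="counts",
        description=(
            "Isodecoder read-count tables for wild-type (AGA) vs mistranslating "
            "(AAA) samples, 3 biological replicates each."
        ),
        payload={"count_means": _fig2_count_means(), "n_replicates": 3},
        ground_truth={
            "mutant_mean_AAA": 26.0,
            "mutant_mean_AGA": 0.5,
            "ser_aga_pool_mean": 2000.0,
            "lys_ttt_fold_AGA_over_AAA": 1.8,
            "mt_cys_fold_AGA_over_AAA": 1.5,
            "phe_pool_mean": 1857.0,
        },
    )

    # -- cytotoxicity plate -------------------------------------------------
    # Absolute dead/total ratios chosen to satisfy, simultaneously, every
    # printed pairwise relation; the control is the wild-type tRNA + reporter
    # alone ("AGA/mCherry").
    death_ratios = {
        "none/mCherry": 0.1000,
        "AGA/mCherry": 0.1000,
        "AAA/mCherry": 0.1100,
        "none/FUS": 0.10697,
        "AGA/FUS": 0.10700,
        "AAA/FUS": 0.11500,
        "none/R521C": 0.11260,
        "AGA/R521C": 0.11700,
        "AAA/R521C": 0.14976,
    }
    presets["fig4"] = Preset(
        name="fig4",
        kind="toxicity",
        description=(
            "Dye-exclusion toxicity: dead/total fluorescence ratios for 9 "
            "tRNA x reporter conditions, 5 replicates; the mutant-tRNA + "
            "mutant-FUS condition is 40% above the no-tRNA + wild-type-FUS one."
        ),
        payload={
            "death_ratios": death_ratios,
            "post_lysis_mean": 10_000.0,
            "noise_sigma_log": 0.08,
            "n_replicates": 5,
            "control": "AGA/mCherry",
        },
        ground_truth={
            "death_ratios": death_ratios,
            "pct_higher_AAA_R521C_vs_none_FUS": 40.0,
            "pct_higher_AAA_R521C_vs_none_R521C": 33.0,
            "pct_higher_AAA_R521C_vs_AGA_R521C": 28.0,
            "pct_higher_AAA_mCherry_vs_none_mCherry": 10.0,
            "pct_higher_AGA_R521C_vs_AGA_mCherry": 17.0,
        },
    )

    # -- FUS fluorescence kinetics endpoint --------------------------------
    fig5_conditions = {
        "none/FUS": {"intensity_factor": 1.00},
        "AGA/FUS": {"intensity_factor": 2.30},
        "AAA/FUS": {"intensity_factor": 2.30 / 2.50},
        "none/R521C": {"intensity_factor": 1.00},
        "AGA/R521C": {"intensity_factor": 2.00},
        "AAA/R521C": {"intensity_factor": 2.00 / 2.10},
    }
    presets["fig5"] = Preset(
        name="fig5",
        kind="imaging",
        description=(
            "Per-cell FUS reporter fluorescence at the end of the time lapse: "
            "wild-type tRNA raises it 2.3-fold (2.0-fold for the mutant FUS "
            "allele); the mistranslating tRNA lowers it 2.5-fold (2.1-fold) "
            "relative to wild-type tRNA."
        ),
        base_config=GeneratorConfig(
            frame_shape=(512, 512),
            n_cells=150,
            transfected_fraction=1.0,
            cell_radius_px=(10.0, 1.5),
            cell_mean_intensity=60.0,
            background_level=2.0,
            background_noise_sd=0.5,
            aggregates_per_cell_lambda=LAMBDA_BASELINE,
            aggregate_radius_px=1.3,
            aggregate_intensity_multiplier=12.0,
            n_replicates=5,
        ),
        conditions=fig5_conditions,
        ground_truth={
            "fold_AGA_over_none_FUS": 2.3,
            "fold_AGA_over_AAA_FUS": 2.5,
            "fold_AGA_over_none_R521C": 2.0,
            "fold_AGA_over_AAA_R521C": 2.1,
        },
    )

    # -- aggregation kinetics, wild-type FUS -------------------------------
    # Large fields (~200 cells of ~57 px radius in a 3250 px frame) keep the
    # foci area fraction inside the cell mask low enough that the 18-SD
    # threshold detects essentially all foci in every condition; see
    # docs/methods.md for the derivation.
    times = tuple(np.linspace(25.0, 68.5, 20))
    presets["fig6-FUS"] = Preset(
        name="fig6-FUS",
        kind="timelapse",
        description=(
            "Aggregates-per-cell time course for wild-type FUS: wild-type tRNA "
            "5-fold above the no-tRNA baseline at the start, 4-fold at the end; "
            "the mistranslating tRNA rises from 1-fold to 2-fold."
        ),
        base_config=GeneratorConfig(
            frame_shape=(3250, 3250),
            n_cells=200,
            transfected_fraction=1.0,
            cell_radius_px=(57.0, 3.0),
            cell_mean_intensity=100.0,
            background_level=2.0,
            background_noise_sd=0.5,
            aggregate_radius_px=1.3,
            aggregate_intensity_multiplier=100.0,
            rupture_rate=0.0,
            n_replicates=4,
        ),
        conditions={
            "none": {"lambda_knots": [(25.0, 1.0), (68.5, 1.0)]},
            "AGA": {"lambda_knots": [(25.0, 5.0), (68.5, 4.0)]},
            "AAA": {"lambda_knots": [(25.0, 1.0), (68.5, 2.0)]},
        },
        times=times,
        ground_truth={
            "fold_AGA_over_none_start": 5.0,
            "fold_AGA_over_none_end": 4.0,
            "fold_AAA_over_none_end": 2.0,
            "lambda_baseline": LAMBDA_BASELINE,
        },
    )

    # -- aggregation kinetics, mutant FUS, with rupture ---------------------
    presets["fig6-R521C"] = Preset(
        name="fig6-R521C",
        kind="timelapse",
        description=(
            "Aggregates-per-cell time course for the aggregation-prone FUS "
            "variant: wild-type tRNA 4-fold above baseline; the mistranslating "
            "tRNA accelerates mid-course to a 3-fold plateau while cells rupture."
        ),
        base_config=GeneratorConfig(
            frame_shape=(2530, 2530),
            n_cells=200,
            transfected_fraction=1.0,
            cell_radius_px=(45.0, 3.0),
            cell_mean_intensity=100.0,
            background_level=2.0,
            background_noise_sd=0.5,
            aggregate_radius_px=1.3,
            aggregate_intensity_multiplier=100.0,
            rupture_rate=0.0,
            n_replicates=4,
        ),
        conditions={
            "none": {"lambda_knots": [(25.0, 1.0), (68.5, 1.0)]},
            "AGA": {"lambda_knots": [(25.0, 4.0), (68.5, 4.0)]},
            "AAA": {
                "lambda_knots": [(25.0, 1.0), (51.0, 3.0), (68.5, 3.0)],
                "rupture_rate": 0.05,
            },
        },
        times=times,
        ground_truth={
            "plateau_fold_AAA_over_none": 3.0,
            "rupture_rate_AAA": 0.05,
            "lambda_baseline": LAMBDA_BASELINE,
        },
    )

    # -- SDD-AGE lanes -------------------------------------------------------
    lane_fractions = {
        "AGA/FUS": 0.40,
        "AAA/FUS": 0.20,
        "AGA/R521C": 0.48,
        "AAA/R521C": 0.36,
    }
    presets["fig7"] = Preset(
        name="fig7",
        kind="lanes",
        description=(
            "SDD-AGE densitometry lanes: the mistranslating tRNA halves the "
            "aggregated fraction of wild-type FUS and leaves the mutant FUS "
            "aggregated signal at 75% of the wild-type-tRNA level."
        ),
        payload={
            "fractions": lane_fractions,
            "total_area": 1000.0,
            "n_replicates": 3,
        },
        ground_truth={
            "fractions": lane_fractions,
            "fold_reduction_FUS_AGA_over_AAA": 2.0,
            "pct_R521C_AAA_over_AGA": 75.0,
        },
    )

    # -- tiny smoke-test scenario ------------------------------------------
    presets["demo"] = Preset(
        name="demo",
        kind="imaging",
        description="Small two-condition scenario for smoke tests and docs.",
        base_config=GeneratorConfig(
            frame_shape=(360, 360),
            n_cells=40,
            transfected_fraction=1.0,
            cell_radius_px=(10.0, 1.5),
            cell_mean_intensity=100.0,
            background_level=2.0,
            background_noise_sd=0.5,
            aggregates_per_cell_lambda=0.3,
            aggregate_intensity_multiplier=8.0,
            n_replicates=2,
        ),
        conditions={
            "control": {"intensity_factor": 1.0},
            "boosted": {"intensity_factor": 1.5},
        },
        ground_truth={"intensity_ratio": {"boosted/control": 1.5}},
    )

    return presets


PRESETS: dict[str, Preset] = _build_presets()


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def list_presets() -> list[str]:
    return sorted(PRESETS)
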