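"""Synthetic data with known ground truth for every stage of the pipeline.

Generates fields of soft-edged fluorescent cells with bright sub-cellular
foci, time-lapses with cell-rupture events, Poisson tRNA count tables,
two-point dye-exclusion toxicity plates, and SDD-AGE lane profiles.
Every generator is deterministic given (configuration, seed).

The imaging model is deliberately minimal: cells are soft-edged disks
(radial cosine falloff over 2 px) at non-overlapping random centres;
transfected cells carry a diffuse intensity drawn lognormally around
``cell_mean_intensity``; foci are small flat-topped disks whose pixels sit at
``cell intensity x aggregate_intensity_multiplier``; background is Gaussian.
The downstream pipeline uses only areas and intensities, so no realistic
morphology, optics or photobleaching is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .segquant import Frame

__all__ = [
    "GeneratorConfig",
    "CellTruth",
    "FrameTruth",
    "TimelapseTruth",
    "RuptureLogEntry",
    "LaneProfile",
    "LaneTruth",
    "PlacementError",
    "generate_frame",
    "generate_timelapse",
    "generate_count_table",
    "generate_toxicity_plate",
    "generate_lane_profile",
]

SOFT_EDGE_PX = 2.0  # width of the cosine intensity falloff at the cell rim


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails within the retry budget."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic imaging model.

    Intensities are AU; radii and the frame shape are pixels;
    ``aggregates_per_cell_lambda`` is the expected number of foci per
    transfected cell and may be a callable of time (hours) for time-lapses;
    ``rupture_rate`` is the per-cell per-frame-transition probability that a
    transfected cell ruptures (disappears with its foci from later frames).
    """

    frame_shape: tuple[int, int] = (512, 512)
    n_cells: int = 100
    transfected_fraction: float = 1.0
    cell_radius_px: tuple[float, float] = (10.0, 1.5)  # (mean, spread)
    cell_mean_intensity: float = 100.0
    intensity_sigma_log: float = 0.2
    background_level: float = 2.0
    background_noise_sd: float = 0.5
    aggregates_per_cell_lambda: float | Callable[[float], float] = 0.0
    aggregate_radius_px: float = 1.3
    aggregate_intensity_multiplier: float = 100.0
    rupture_rate: float = 0.0
    n_replicates: int = 4
    seed: int | None = None

    def validate(self) -> None:
        if not (0.0 <= self.transfected_fraction <= 1.0):
            raise ValueError("transfected_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if min(self.frame_shape) < 8:
            raise ValueError("frame too small")
        if (
            self.cell_mean_intensity < 0
            or self.background_level < 0
            or self.background_noise_sd < 0
        ):
            raise ValueError("intensities must be >= 0")
        if self.aggregate_intensity_multiplier <= 1.0:
            raise ValueError("aggregate_intensity_multiplier must be > 1")
        if not (0.0 <= self.rupture_rate <= 1.0):
            raise ValueError("rupture_rate must be in [0, 1]")
        if not callable(self.aggregates_per_cell_lambda):
            if self.aggregates_per_cell_lambda < 0:
                raise ValueError("aggregates_per_cell_lambda must be >= 0")

    def lambda_at(self, time_h: float) -> float:
        lam = self.aggregates_per_cell_lambda
        value = float(lam(time_h)) if callable(lam) else float(lam)
        if value < 0:
            raise ValueError("aggregates_per_cell_lambda must be >= 0")
        return value


@dataclass
class CellTruth:
    center: tuple[float, float]  # (row, col)
    radius: float
    transfected: bool
    intensity: float  # diffuse AU (0 for untransfected)
    foci_count: int = 0
    foci_centers: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class FrameTruth:
    n_cells: int
    n_transfected: int
    total_foci: int
    lambda_used: float
    time_h: float
    cells: list[CellTruth]


@dataclass
class RuptureLogEntry:
    cell_index: int
    time_h: float  # first time point at which the cell is gone


@dataclass
class TimelapseTruth:
    frames: list[FrameTruth]
    ruptures: list[RuptureLogEntry]
    alive_matrix: np.ndarray  # (n_frames, n_cells) bool


# ---------------------------------------------------------------------------
# layout + rendering
# ---------------------------------------------------------------------------

def _place_cells(cfg: GeneratorConfig, rng: np.random.Generator, margin: float = 2.0):
    """Non-overlapping random centres by dart throwing with bounded retries."""
    h, w = cfg.frame_shape
    r_mean, r_spread = cfg.cell_radius_px
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    cy = np.empty(0)
    cx = np.empty(0)
    cr = np.empty(0)
    max_attempts = 500
    for _ in range(cfg.n_cells):
        r = float(np.clip(rng.normal(r_mean, r_spread), 0.4 * r_mean, 1.8 * r_mean))
        for _attempt in range(max_attempts):
            y = rng.uniform(r + 1, h - r - 1)
            x = rng.uniform(r + 1, w - r - 1)
            if cy.size:
                if np.any((cy - y) ** 2 + (cx - x) ** 2 < (cr + r + margin) ** 2):
                    continue
            break
        else:
            raise PlacementError(
                f"could not place {cfg.n_cells} non-overlapping cells of radius "
                f"~{r_mean:.0f}px in a {h}x{w} frame"
            )
        centers.append((y, x))
        radii.append(r)
        cy = np.append(cy, y)
        cx = np.append(cx, x)
        cr = np.append(cr, r)
    return centers, radii


def _soft_disk_weights(r: float, dist: np.ndarray) -> np.ndarray:
    """1 inside r - SOFT_EDGE_PX, cosine falloff to 0 at r."""
    w = np.zeros_like(dist, dtype=np.float32)
    inner = r - SOFT_EDGE_PX
    w[dist <= inner] = 1.0
    edge = (dist > inner) & (dist < r)
    w[edge] = 0.5 * (1.0 + np.cos(np.pi * (dist[edge] - inner) / SOFT_EDGE_PX))
    return w


def _render_cell(img: np.ndarray, center, radius: float, intensity: float) -> None:
    h, w = img.shape
    y, x = center
    y0, y1 = max(int(y - radius) - 1, 0), min(int(y + radius) + 2, h)
    x0, x1 = max(int(x - radius) - 1, 0), min(int(x + radius) + 2, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - y, xx - x)
    img[y0:y1, x0:x1] += intensity * _soft_disk_weights(radius, dist)


def _render_focus(img: np.ndarray, center, radius: float, intensity: float) -> None:
    """Flat-topped focus: every pixel whose centre lies within ``radius`` is
    raised to ``intensity`` (foci are saturated relative to the diffuse pool)."""
    h, w = img.shape
    y, x = center
    y0, y1 = max(int(y - radius) - 1, 0), min(int(y + radius) + 2, h)
    x0, x1 = max(int(x - radius) - 1, 0), min(int(x + radius) + 2, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = np.hypot(yy - y, xx - x) <= radius
    patch = img[y0:y1, x0:x1]
    patch[inside] = np.maximum(patch[inside], intensity)


def _draw_foci_positions(
    cell: CellTruth, k: int, cfg: GeneratorConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Foci centres uniformly inside the cell, kept clear of the soft rim so
    each focus lies fully within its parent cell mask."""
    rmax = max(cell.radius - SOFT_EDGE_PX - cfg.aggregate_radius_px - 1.0, 1.0)
    out: list[tuple[float, float]] = []
    min_sep = 2.0 * cfg.aggregate_radius_px + 1.0
    for _ in range(k):
        for _attempt in range(50):
            rho = rmax * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            p = (cell.center[0] + rho * math.sin(theta), cell.center[1] + rho * math.cos(theta))
            if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in out):
                break
        out.append(p)
    return out


def _sample_layout(cfg: GeneratorConfig, rng: np.random.Generator) -> list[CellTruth]:
    centers, radii = _place_cells(cfg, rng)
    cells = []
    for c, r in zip(centers, radii):
        transfected = bool(rng.random() < cfg.transfected_fraction)
        intensity = (
            float(cfg.cell_mean_intensity * rng.lognormal(0.0, cfg.intensity_sigma_log))
            if transfected
            else 0.0
        )
        cells.append(CellTruth(center=c, radius=r, transfected=transfected, intensity=intensity))
    return cells


def _render_frame(
    cfg: GeneratorConfig,
    cells: Sequence[CellTruth],
    rng: np.random.Generator,
    time_h: float,
    condition: str,
    replicate: str,
) -> Frame:
    img = np.zeros(cfg.frame_shape, dtype=np.float32)
    for cell in cells:
        if cell.intensity > 0:
            _render_cell(img, cell.center, cell.radius, cell.intensity)
            for p in cell.foci_centers:
                _render_focus(
                    img, p, cfg.aggregate_radius_px,
                    cell.intensity * cfg.aggregate_intensity_multiplier,
                )
    img += cfg.background_level
    if cfg.background_noise_sd > 0:
        noise = rng.standard_normal(cfg.frame_shape, dtype=np.float32)
        np.multiply(noise, np.float32(cfg.background_noise_sd), out=noise)
        img += noise
    np.clip(img, 0.0, None, out=img)
    return Frame(pixels=img, time_h=time_h, condition=condition, replicate=replicate)


def generate_frame(
    config: GeneratorConfig,
    time_h: float = 0.0,
    seed: int | None = None,
    condition: str = "",
    replicate: str = "",
) -> tuple[Frame, FrameTruth]:
    """One synthetic field of view plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cells = _sample_layout(config, rng)
    lam = config.lambda_at(time_h)
    for cell in cells:
        if cell.transfected:
            k = int(rng.poisson(lam))
            cell.foci_count = k
            cell.foci_centers = _draw_foci_positions(cell, k, config, rng)
    frame = _render_frame(config, cells, rng, time_h, condition, replicate)
    truth = FrameTruth(
        n_cells=len(cells),
        n_transfected=sum(c.transfected for c in cells),
        total_foci=sum(c.foci_count for c in cells),
        lambda_used=lam,
        time_h=time_h,
        cells=cells,
    )
    return frame, truth


def generate_timelapse(
    config: GeneratorConfig,
    times: Sequence[float],
    trajectory: Callable[[float], float] | None = None,
    rupture_rate: float | None = None,
    seed: int | None = None,
    condition: str = "",
    replicate: str = "",
) -> tuple[list[Frame], TimelapseTruth]:
    """A time-lapse with persistent cells, per-frame Poisson foci counts and
    optional rupture events.

    ``trajectory`` overrides ``config.aggregates_per_cell_lambda`` as λ(t).
    A ruptured cell is removed together with its foci from that frame onward
    (the released fluorescence leaves the field); rupture times are logged.
    """
    config.validate()
    times = [float(t) for t in times]
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    lam_of_t = trajectory if trajectory is not None else config.lambda_at
    rate = config.rupture_rate if rupture_rate is None else float(rupture_rate)
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rupture_rate must be in [0, 1]")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = _sample_layout(config, rng)
    alive = np.ones(len(layout), dtype=bool)
    alive_matrix = np.zeros((len(times), len(layout)), dtype=bool)
    frames: list[Frame] = []
    frame_truths: list[FrameTruth] = []
    ruptures: list[RuptureLogEntry] = []

    for i, t in enumerate(times):
        if i > 0 and rate > 0:
            for j, cell in enumerate(layout):
                if alive[j] and cell.transfected and rng.random() < rate:
                    alive[j] = False
                    ruptures.append(RuptureLogEntry(cell_index=j, time_h=t))
        alive_matrix[i] = alive
        lam = float(lam_of_t(t))
        if lam < 0:
            raise ValueError("trajectory produced a negative rate")
        current: list[CellTruth] = []
        for j, cell in enumerate(layout):
            if not alive[j]:
                continue
            c = CellTruth(
                center=cell.center,
                radius=cell.radius,
                transfected=cell.transfected,
                intensity=cell.intensity,
            )
            if c.transfected:
                k = int(rng.poisson(lam))
                c.foci_count = k
                c.foci_centers = _draw_foci_positions(c, k, config, rng)
            current.append(c)
        frames.append(_render_frame(config, current, rng, t, condition, replicate))
        frame_truths.append(
            FrameTruth(
                n_cells=len(current),
                n_transfected=sum(c.transfected for c in current),
                total_foci=sum(c.foci_count for c in current),
                lambda_used=lam,
                time_h=t,
                cells=current,
            )
        )
    truth = TimelapseTruth(frames=frame_truths, ruptures=ruptures, alive_matrix=alive_matrix)
    return frames, truth


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def generate_count_table(
    count_means: pd.DataFrame,
    n_replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Poisson read-count table from per-transcript, per-condition means.

    ``count_means`` needs columns ``transcript_id``, ``mapping_class``
    (``unique``/``multi``), optionally ``family``, plus one numeric column per
    condition holding the expected count. Output: one row per transcript with
    the metadata columns and one count column per sample named
    ``{condition}_{replicate}``. Counts are independent Poisson draws.
    """
    meta_cols = [c for c in ("transcript_id", "mapping_class", "family") if c in count_means]
    if "transcript_id" not in meta_cols or "mapping_class" not in meta_cols:
        raise ValueError("count_means needs transcript_id and mapping_class columns")
    conditions = [c for c in count_means.columns if c not in meta_cols]
    if not conditions:
        raise ValueError("count_means has no condition columns")
    bad = ~count_means["mapping_class"].isin(["unique", "multi"])
    if bad.any():
        raise ValueError("mapping_class must be 'unique' or 'multi'")
    rng = np.random.default_rng(seed)
    out = count_means[meta_cols].copy()
    for cond in conditions:
        means = count_means[cond].to_numpy(dtype=float)
        if np.any(means < 0):
            raise ValueError(f"negative mean count in condition {cond!r}")
        for rep in range(1, n_replicates + 1):
            out[f"{cond}_{rep}"] = rng.poisson(means)
    return out


# ---------------------------------------------------------------------------
# toxicity plates
# ---------------------------------------------------------------------------

def generate_toxicity_plate(
    death_ratios: dict[str, float],
    post_lysis_mean: float = 10_000.0,
    noise_sigma_log: float = 0.08,
    n_replicates: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Dye-exclusion plate readings: per condition and replicate, a
    post-lysis (total cells) fluorescence drawn lognormally around
    ``post_lysis_mean`` and a pre-lysis (dead cells) fluorescence equal to
    ``post x injected death ratio x lognormal noise``."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond, ratio in death_ratios.items():
        if ratio < 0:
            raise ValueError("death ratios must be >= 0")
        for rep in range(1, n_replicates + 1):
            post = post_lysis_mean * rng.lognormal(0.0, noise_sigma_log)
            pre = post * ratio * rng.lognormal(0.0, noise_sigma_log)
            rows.append(
                {"condition": cond, "replicate": rep, "pre_lysis": pre, "post_lysis": post}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SDD-AGE lane profiles
# ---------------------------------------------------------------------------

@dataclass
class LaneProfile:
    """1-D densitometry trace of one electrophoresis lane.

    ``positions`` are migration distances (arbitrary units) increasing from
    the high-molecular-weight end of the lane toward the monomer band;
    ``signal`` is the non-negative densitometry value.
    """

    positions: np.ndarray
    signal: np.ndarray
    monomer_window: tuple[float, float] | None = None
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.signal.shape:
            raise ValueError("positions and signal must be matching 1-D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class LaneTruth:
    fraction_aggregated: float
    monomer_area: float
    smear_area: float


def generate_lane_profile(
    fraction_aggregated: float,
    total_area: float = 1000.0,
    lane_length: float = 100.0,
    n_points: int = 501,
    monomer_position: float = 70.0,
    monomer_sigma: float = 2.5,
    smear_origin: float = 35.0,
    smear_sigma: float = 12.0,
    baseline_offset: float = 1.0,
    noise_sd: float = 0.1,
    seed: int | None = None,
    condition: str = "",
    replicate: str = "",
) -> tuple[LaneProfile, LaneTruth]:
    """One lane: a Gaussian monomer peak plus a half-Gaussian smear decaying
    toward the high-molecular-weight end, on a constant offset with smooth
    noise. The two component areas split ``total_area`` according to the
    injected aggregated fraction."""
    if not (0.0 <= fraction_aggregated <= 1.0):
        raise ValueError("fraction_aggregated must be in [0, 1]")
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, lane_length, n_points)
    monomer_area = total_area * (1.0 - fraction_aggregated)
    smear_area = total_area * fraction_aggregated

    monomer = np.exp(-0.5 * ((x - monomer_position) / monomer_sigma) ** 2)
    monomer *= monomer_area / np.trapezoid(monomer, x) if monomer.any() else 0.0

    smear = np.where(
        x <= smear_origin, np.exp(-0.5 * ((x - smear_origin) / smear_sigma) ** 2), 0.0
    )
    s_int = np.trapezoid(smear, x)
    smear = smear * (smear_area / s_int) if s_int > 0 and smear_area > 0 else np.zeros_like(x)

    if noise_sd > 0:
        # densitometry noise is spatially smooth; rescale after filtering so
        # the realised SD equals noise_sd
        noise = gaussian_filter1d(rng.standard_normal(n_points), sigma=10.0)
        noise *= noise_sd / max(noise.std(), 1e-12)
    else:
        noise = np.zeros(n_points)
    signal = np.clip(monomer + smear + baseline_offset + noise, 0.0, None)

    profile = LaneProfile(
        positions=x, signal=signal, condition=condition, replicate=replicate
    )
    truth = LaneTruth(
        fraction_aggregated=fraction_aggregated,
        monomer_area=monomer_area,
        smear_area=smear_area,
    )
    return profile, truth
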