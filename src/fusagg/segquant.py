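"""Cell segmentation, intensity-threshold aggregate detection and
median-size-adjusted counting.

The quantification scheme mirrors a semi-automated live-cell imaging macro:

1. Estimate background statistics robustly (tail-excluded, truncation-corrected).
2. Segment fluorescing cell area as connected components above
   ``background_mean + k_cell * background_sd``.
3. Detect aggregates as connected components of pixels brighter than
   ``mean + k_sigma * SD`` of the pixel intensities inside the cell mask
   (``k_sigma`` defaults to the stringent value 18).
4. Convert total areas into (fractional) object counts by dividing by the
   experiment-wide *median* cell area and median aggregate area
   ("median size adjustment"), so that
   ``aggregates_per_cell = aggregate_count / cell_count``.

All intensities are arbitrary fluorescence units (AU); coordinates are
row-major, 0-based; connectivity is 8-neighbour.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from skimage.measure import label

logger = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "BackgroundStats",
    "SegmentationResult",
    "MedianCalibration",
    "FrameQuant",
    "estimate_background",
    "segment_cells",
    "detect_aggregates",
    "segment_frame",
    "calibrate_medians",
    "quantify_frame",
    "transfection_efficiency",
]


@dataclass
class Frame:
    """A single-channel fluorescence image plus acquisition metadata.

    ``pixels`` is a 2-D grid of finite, non-negative intensities (AU).
    ``condition`` encodes the experimental condition label
    (e.g. ``"AGA/FUS"``), ``time_h`` is hours post-transfection.
    """

    pixels: np.ndarray
    time_h: float = 0.0
    condition: str = ""
    replicate: str = ""
    channel: str = "RFP"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("Frame.pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Frame.pixels must be finite")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("Frame.pixels must be non-negative")


@dataclass(frozen=True)
class BackgroundStats:
    mean: float
    sd: float
    degenerate: bool = False


@dataclass
class SegmentationResult:
    """Masks, component areas and summary statistics for one frame."""

    background_mean: float
    background_sd: float
    cell_mask: np.ndarray
    aggregate_mask: np.ndarray
    cell_components: list[int]
    aggregate_components: list[int]
    cell_pixel_mean: float
    cell_pixel_sd: float
    threshold_used: float
    k_sigma: float
    cell_intensity_sum: float
    time_h: float = 0.0
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if np.any(self.aggregate_mask & ~self.cell_mask):
            raise ValueError("aggregate_mask must be a subset of cell_mask")


@dataclass(frozen=True)
class MedianCalibration:
    """Experiment-wide median object areas shared by all frames of one
    experiment (all conditions and time points pooled)."""

    median_cell_area: float
    median_aggregate_area: float | None
    n_frames_pooled: int


@dataclass(frozen=True)
class FrameQuant:
    """Per-frame quantities after median size adjustment.

    Counts are fractional by design (area ratios); ``aggregates_per_cell``
    and ``fluorescence_per_cell`` are NaN when no cell area was found.
    """

    total_cell_area: float
    total_aggregate_area: float
    cell_count: float
    aggregate_count: float
    aggregates_per_cell: float
    total_fluorescence: float
    fluorescence_per_cell: float
    threshold_used: float
    k_sigma: float
    time_h: float = 0.0
    condition: str = ""
    replicate: str = ""


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------

def _truncated_moment_correction(m: float, v: float, tau: float) -> tuple[float, float]:
    """Recover (mu, sigma) of a Gaussian from the mean/variance of its
    upper-truncated sample {x < tau}.

    For X ~ N(mu, sigma^2) truncated to X < tau with xi = (tau - mu)/sigma and
    h = phi(xi)/Phi(xi):

        E[X | X < tau]   = mu - sigma * h
        Var[X | X < tau] = sigma^2 * (1 - xi*h - h^2)

    so v / (tau - m)^2 = (1 - xi*h - h^2) / (xi + h)^2 =: R(xi), which is
    monotone in xi and solved by bisection.
    """
    gap = tau - m
    if gap <= 0 or v <= 0:
        return m, math.sqrt(max(v, 0.0))

    def ratio(xi: float) -> float:
        h = norm.pdf(xi) / norm.cdf(xi)
        return (1.0 - xi * h - h * h) / (xi + h) ** 2

    target = v / gap**2
    lo, hi = -8.0, 8.0
    try:
        if not (ratio(hi) <= target <= ratio(lo)):
            return m, math.sqrt(v)
        xi = brentq(lambda x: ratio(x) - target, lo, hi, xtol=1e-10)
    except ValueError:  # pragma: no cover - numerical corner
        return m, math.sqrt(v)
    h = norm.pdf(xi) / norm.cdf(xi)
    sigma = gap / (xi + h)
    mu = m + sigma * h
    return mu, sigma


def estimate_background(frame: Frame, tail_quantile: float = 0.75) -> BackgroundStats:
    """Robust background mean/SD from the pixel population.

    Pixels above the ``tail_quantile`` quantile (bright cells, foci,
    saturated pixels) are excluded; the moments of the remaining sample are
    corrected for the truncation under a Gaussian background model, so a
    pure-noise frame is recovered without bias.

    An all-identical frame returns ``sd = 0`` flagged degenerate.
    """
    px = np.asarray(frame.pixels, dtype=np.float64).ravel()
    if px.size == 0:
        raise ValueError("empty frame")
    if np.ptp(px) == 0:
        return BackgroundStats(float(px[0]), 0.0, degenerate=True)
    # moments of the background population are estimated on a strided
    # subsample for large frames (>=2M pixels retained: negligible error)
    stride = max(1, px.size // 2_000_000)
    px = px[::stride]
    tau = float(np.quantile(px, tail_quantile))
    sub = px[px < tau]
    if sub.size < 2:
        return BackgroundStats(float(px.mean()), float(px.std()), degenerate=True)
    mu, sigma = _truncated_moment_correction(float(sub.mean()), float(sub.var()), tau)
    return BackgroundStats(mu, sigma, degenerate=sigma == 0.0)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _filtered_components(
    binary: np.ndarray, min_area: int
) -> tuple[np.ndarray, list[int]]:
    """8-connected components of ``binary`` with small ones removed.

    Returns the cleaned boolean mask and the retained component areas
    (label order), so that ``sum(areas) == mask.sum()``.
    """
    labels = label(binary, connectivity=2)
    n_labels = int(labels.max())
    if n_labels == 0:
        return np.zeros_like(binary, dtype=bool), []
    flat = labels.ravel()
    areas = np.bincount(flat[flat > 0], minlength=n_labels + 1)[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    if keep.size == 0:
        return np.zeros_like(binary, dtype=bool), []
    lut = np.zeros(labels.max() + 1, dtype=bool)
    lut[keep] = True
    mask = lut[labels]
    return mask, [int(areas[k - 1]) for k in keep]


def segment_cells(
    frame: Frame,
    bg_mean: float,
    bg_sd: float,
    k_cell: float = 3.0,
    min_cell_area_px: int = 20,
    fallback_factor: float = 1.5,
) -> tuple[np.ndarray, list[int]]:
    """Fluorescent cell area: pixels above ``bg_mean + k_cell*bg_sd``.

    Degenerate background (sd = 0) falls back to ``bg_mean * fallback_factor``.
    """
    if bg_sd > 0:
        threshold = bg_mean + k_cell * bg_sd
    else:
        threshold = bg_mean * fallback_factor
        logger.warning(
            "degenerate background (sd=0): cell threshold falls back to %.3g",
            threshold,
        )
    return _filtered_components(frame.pixels > threshold, min_cell_area_px)


def detect_aggregates(
    frame: Frame,
    cell_mask: np.ndarray,
    k_sigma: float = 18.0,
    min_agg_area_px: int = 2,
) -> tuple[np.ndarray, list[int], float, float, float]:
    """Aggregate foci: pixels within the cell mask brighter than
    ``mean + k_sigma * SD`` of the cell-mask pixel intensities.

    Returns (mask, component areas, threshold, cell_pixel_mean, cell_pixel_sd).
    With an empty cell mask (or zero SD, i.e. perfectly uniform cells) no
    pixel can exceed the threshold and the mask is empty.
    """
    if not cell_mask.any():
        warnings.warn("empty cell mask: no aggregates can be detected", stacklevel=2)
        return np.zeros_like(cell_mask, dtype=bool), [], math.nan, math.nan, math.nan
    cell_px = frame.pixels[cell_mask].astype(np.float64)
    m = float(cell_px.mean())
    s = float(cell_px.std())
    threshold = m + k_sigma * s
    binary = (frame.pixels > threshold) & cell_mask
    mask, areas = _filtered_components(binary, min_agg_area_px)
    return mask, areas, threshold, m, s


def segment_frame(
    frame: Frame,
    k_cell: float = 3.0,
    k_sigma: float = 18.0,
    min_cell_area_px: int = 20,
    min_agg_area_px: int = 2,
    tail_quantile: float = 0.75,
) -> SegmentationResult:
    """Run background estimation, cell segmentation and aggregate detection
    on one frame and bundle everything needed for quantification."""
    bg = estimate_background(frame, tail_quantile=tail_quantile)
    cell_mask, cell_areas = segment_cells(
        frame, bg.mean, bg.sd, k_cell=k_cell, min_cell_area_px=min_cell_area_px
    )
    if cell_mask.any():
        # single pass over the cell pixels: threshold statistics and the
        # intensity sum share one boolean gather
        cell_px = frame.pixels[cell_mask].astype(np.float64)
        cpm = float(cell_px.mean())
        cps = float(cell_px.std())
        thr = cpm + k_sigma * cps
        agg_mask, agg_areas = _filtered_components(
            (frame.pixels > thr) & cell_mask, min_agg_area_px
        )
        cell_sum = float(cell_px.sum())
    else:
        agg_mask = np.zeros_like(cell_mask, dtype=bool)
        agg_areas, thr, cpm, cps = [], math.nan, math.nan, math.nan
        cell_sum = 0.0
    return SegmentationResult(
        background_mean=bg.mean,
        background_sd=bg.sd,
        cell_mask=cell_mask,
        aggregate_mask=agg_mask,
        cell_components=cell_areas,
        aggregate_components=agg_areas,
        cell_pixel_mean=cpm,
        cell_pixel_sd=cps,
        threshold_used=thr,
        k_sigma=k_sigma,
        cell_intensity_sum=cell_sum,
        time_h=frame.time_h,
        condition=frame.condition,
        replicate=frame.replicate,
    )


# ---------------------------------------------------------------------------
# median size adjustment
# ---------------------------------------------------------------------------

def calibrate_medians(results: Iterable[SegmentationResult]) -> MedianCalibration:
    """Median cell and aggregate component areas pooled over every frame of
    one experiment (all conditions and time points).

    The medians are shared by all frames so the counts of different
    conditions are on a common scale. An experiment without any aggregate
    component leaves the aggregate median undefined (aggregate counts are
    then 0). An experiment without any cell component is an error.
    """
    results = list(results)
    cell_areas: list[int] = []
    agg_areas: list[int] = []
    for r in results:
        cell_areas.extend(r.cell_components)
        agg_areas.extend(r.aggregate_components)
    if not cell_areas:
        raise ValueError("no cell components in any frame: nothing to calibrate")
    return MedianCalibration(
        median_cell_area=float(np.median(cell_areas)),
        median_aggregate_area=float(np.median(agg_areas)) if agg_areas else None,
        n_frames_pooled=len(results),
    )


def quantify_frame(seg: SegmentationResult, calib: MedianCalibration) -> FrameQuant:
    """Median-size-adjusted counts and per-cell fluorescence for one frame.

    ``cell_count = total_cell_area / median_cell_area`` (fractional),
    likewise for aggregates. ``total_fluorescence`` is the
    background-corrected integrated density over the cell mask
    (sum of pixel - background_mean, clamped at 0).
    """
    total_cell_area = float(np.sum(seg.cell_components))
    total_agg_area = float(np.sum(seg.aggregate_components))
    cell_count = total_cell_area / calib.median_cell_area
    if calib.median_aggregate_area:
        agg_count = total_agg_area / calib.median_aggregate_area
    else:
        agg_count = 0.0
    total_fluor = max(seg.cell_intensity_sum - seg.background_mean * total_cell_area, 0.0)
    if cell_count > 0:
        apc = agg_count / cell_count
        fpc = total_fluor / cell_count
    else:
        apc = math.nan
        fpc = math.nan
    return FrameQuant(
        total_cell_area=total_cell_area,
        total_aggregate_area=total_agg_area,
        cell_count=cell_count,
        aggregate_count=agg_count,
        aggregates_per_cell=apc,
        total_fluorescence=total_fluor,
        fluorescence_per_cell=fpc,
        threshold_used=seg.threshold_used,
        k_sigma=seg.k_sigma,
        time_h=seg.time_h,
        condition=seg.condition,
        replicate=seg.replicate,
    )


def transfection_efficiency(
    frames: Sequence[Frame],
    total_cells: Sequence[int],
    k_cell: float = 3.0,
    min_cell_area_px: int = 20,
    tail_quantile: float = 0.75,
) -> float:
    """Fraction of cells that visibly fluoresce.

    Fluorescing cells are counted as segmented cell components per frame;
    ``total_cells`` supplies the true per-frame totals (e.g. from a
    brightfield count or a synthetic ground-truth sidecar). Counts are
    pooled across frames.
    """
    if len(frames) != len(total_cells):
        raise ValueError("need one total-cell count per frame")
    if len(frames) == 0:
        raise ValueError("no frames")
    if any(t <= 0 for t in total_cells):
        raise ValueError("total cell counts must be positive")
    fluorescing = 0
    for fr in frames:
        bg = estimate_background(fr, tail_quantile=tail_quantile)
        _, areas = segment_cells(
            fr, bg.mean, bg.sd, k_cell=k_cell, min_cell_area_px=min_cell_area_px
        )
        fluorescing += len(areas)
    return fluorescing / float(np.sum(total_cells))
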