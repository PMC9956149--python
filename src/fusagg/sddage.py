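"""SDD-AGE densitometry: aggregated-protein fraction from a 1-D lane profile.

Semi-denaturing detergent agarose gel electrophoresis resolves monomeric
protein (a sharp low-molecular-weight band) from SDS-resistant aggregates
(a broad high-molecular-weight smear). The aggregated fraction of a lane is
the integrated signal outside the monomer band divided by the total lane
signal, after baseline subtraction — a within-lane ratio, so no cross-lane
loading normalization is applied and the result is invariant under uniform
scaling of the signal.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.optimize import curve_fit

from .imgsim import LaneProfile

__all__ = ["subtract_baseline", "auto_monomer_window", "fraction_aggregated"]


def subtract_baseline(profile: LaneProfile, window_fraction: float = 0.2) -> LaneProfile:
    """Rolling-minimum baseline subtraction.

    The baseline at each position is the minimum signal within a window of
    ``window_fraction`` of the lane length (default 20%, wider than any
    band so peaks are preserved); negatives after subtraction are clamped
    to 0. A flat profile maps to all zeros.
    """
    if not (0.0 < window_fraction <= 1.0):
        raise ValueError("window_fraction must be in (0, 1]")
    n = profile.signal.size
    size = max(int(round(window_fraction * n)), 1)
    baseline = minimum_filter1d(profile.signal, size=size, mode="nearest")
    corrected = np.clip(profile.signal - baseline, 0.0, None)
    return LaneProfile(
        positions=profile.positions.copy(),
        signal=corrected,
        monomer_window=profile.monomer_window,
        condition=profile.condition,
        replicate=profile.replicate,
    )


def _gaussian(x, amplitude, mu, sigma):
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def auto_monomer_window(
    profile: LaneProfile, window_sd: float = 3.0, fit_halfwidth: float = 6.0
) -> tuple[float, float]:
    """Monomer band window from a Gaussian fit of the tallest peak.

    Fits A*exp(-(x-mu)^2 / 2 sigma^2) to the profile within
    ``fit_halfwidth`` positions of the global maximum and returns
    ``mu +- window_sd * sigma``. The monomer band is the tallest feature of
    a lane (the smear is broad and low), so the global maximum locates it.
    """
    x, y = profile.positions, profile.signal
    if not y.any():
        raise ValueError("cannot locate a monomer band in an all-zero profile")
    peak = int(np.argmax(y))
    sel = np.abs(x - x[peak]) <= fit_halfwidth
    try:
        popt, _ = curve_fit(
            _gaussian,
            x[sel],
            y[sel],
            p0=(float(y[peak]), float(x[peak]), fit_halfwidth / 3.0),
            maxfev=5000,
        )
        mu, sigma = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:  # fit failure: fall back to the fit region itself
        mu, sigma = float(x[peak]), fit_halfwidth / 3.0
    return (mu - window_sd * sigma, mu + window_sd * sigma)


def fraction_aggregated(
    profile: LaneProfile,
    monomer_window: tuple[float, float] | None = None,
) -> float:
    """Aggregated fraction: trapezoidal area outside the monomer window
    divided by the total lane area, in [0, 1].

    Expects a baseline-subtracted profile. ``monomer_window`` defaults to
    the profile's stored window or, failing that, the automatic Gaussian
    fit around the tallest peak. A zero total area is undefined (NaN).
    Widening the window can only shrink the result (monotone).
    """
    if monomer_window is None:
        monomer_window = profile.monomer_window or auto_monomer_window(profile)
    lo, hi = sorted(monomer_window)
    x, y = profile.positions, profile.signal
    total = float(np.trapezoid(y, x))
    if total <= 0:
        return math.nan
    inside = np.where((x >= lo) & (x <= hi), y, 0.0)
    monomer = float(np.trapezoid(inside, x))
    return min(max((total - monomer) / total, 0.0), 1.0)
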