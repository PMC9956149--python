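"""Dye-exclusion cytotoxicity: dead/total fluorescence ratios.

A membrane-impermeant dye stains only dead cells; lysing the membranes with
detergent then stains every cell. The per-well readout is the ratio of
fluorescence before (dead cells) to after (total cells) lysis, and
biological replicate means are normalized to a control condition's mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ToxicityRecord", "toxicity_ratio", "normalize_to_control", "plate_ratios"]


@dataclass(frozen=True)
class ToxicityRecord:
    condition: str
    replicate: str | int
    pre_lysis_fluorescence: float  # dead cells
    post_lysis_fluorescence: float  # total cells

    def __post_init__(self) -> None:
        if self.pre_lysis_fluorescence < 0 or self.post_lysis_fluorescence < 0:
            raise ValueError("fluorescence readings must be >= 0")


def toxicity_ratio(rec: ToxicityRecord) -> float:
    """Dead-to-total fluorescence ratio (pre/post lysis), in [0, 1] for
    well-formed wells.

    A malformed well with pre > post is retained at its reported value with
    a warning (transparency over silent clipping); post = 0 is undefined
    and returns NaN with a warning.
    """
    if rec.post_lysis_fluorescence == 0:
        warnings.warn(
            f"well {rec.condition}/{rec.replicate}: post-lysis fluorescence is 0; "
            "ratio undefined",
            stacklevel=2,
        )
        return math.nan
    ratio = rec.pre_lysis_fluorescence / rec.post_lysis_fluorescence
    if ratio > 1:
        warnings.warn(
            f"well {rec.condition}/{rec.replicate}: pre-lysis exceeds post-lysis "
            f"(ratio {ratio:.3f} > 1); retained unclipped",
            stacklevel=2,
        )
    return ratio


def plate_ratios(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well ratios from a plate table with columns
    ``condition, replicate, pre_lysis, post_lysis``."""
    records = [
        ToxicityRecord(r.condition, r.replicate, r.pre_lysis, r.post_lysis)
        for r in plate.itertuples()
    ]
    out = plate[["condition", "replicate"]].copy()
    out["ratio"] = [toxicity_ratio(r) for r in records]
    return out


def normalize_to_control(ratios: pd.DataFrame, control: str) -> pd.DataFrame:
    """Normalize per-condition replicate ratios to the control condition's
    mean ratio.

    ``ratios`` has columns ``condition`` and ``ratio``. Returns one row per
    condition with mean_ratio, normalized_mean, sd (of the normalized
    replicates) and n; the control condition normalizes to exactly 1.
    Scale-invariant: multiplying every fluorescence reading by a positive
    constant leaves the normalized output unchanged.
    """
    if control not in set(ratios["condition"]):
        raise ValueError(f"control condition {control!r} not present")
    control_mean = ratios.loc[ratios["condition"] == control, "ratio"].mean()
    if not control_mean > 0:
        raise ValueError("control mean ratio must be positive")
    rows = []
    for cond, grp in ratios.groupby("condition", sort=False):
        vals = grp["ratio"].to_numpy(dtype=float)
        norm = vals / control_mean
        rows.append(
            {
                "condition": cond,
                "mean_ratio": float(vals.mean()),
                "normalized_mean": float(norm.mean()),
                "sd": float(norm.std(ddof=1)) if norm.size > 1 else 0.0,
                "n": int(norm.size),
            }
        )
    return pd.DataFrame(rows)
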