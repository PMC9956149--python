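"""Readers and writers for the pipeline's on-disk formats.

Images travel as single- or multi-page TIFF with a JSON sidecar holding the
per-frame metadata (time, condition, replicate) and, for synthetic data, the
ground truth. Tables are plain CSV/TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile

from .imgsim import LaneProfile
from .segquant import Frame, SegmentationResult

__all__ = [
    "write_frames_tiff",
    "read_frames_tiff",
    "write_quant_csv",
    "read_quant_csv",
    "write_mask_png",
    "write_count_table_tsv",
    "read_count_table_tsv",
    "write_toxicity_csv",
    "read_toxicity_csv",
    "write_lane_csv",
    "read_lane_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frames_tiff(frames: Sequence[Frame], path: str | Path, ground_truth: Any = None) -> None:
    """Multi-page TIFF (one page per frame) + JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.stack([f.pixels.astype(np.float32) for f in frames]))
    meta = {
        "frames": [
            {"time_h": f.time_h, "condition": f.condition,
             "replicate": f.replicate, "channel": f.channel}
            for f in frames
        ]
    }
    if ground_truth is not None:
        meta["ground_truth"] = _to_jsonable(ground_truth)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_frames_tiff(path: str | Path) -> list[Frame]:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text())["frames"] if sidecar.exists() else None
    frames = []
    for i, page in enumerate(stack):
        m = meta[i] if meta else {}
        frames.append(
            Frame(pixels=page, time_h=m.get("time_h", float(i)),
                  condition=m.get("condition", ""), replicate=m.get("replicate", ""),
                  channel=m.get("channel", "RFP"))
        )
    return frames


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


QUANT_COLUMNS = [
    "time_h", "condition", "replicate", "cell_count", "aggregate_count",
    "aggregates_per_cell", "fluorescence_per_cell", "total_fluorescence",
    "total_cell_area", "total_aggregate_area", "threshold_used", "k_sigma",
]


def write_quant_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[[c for c in QUANT_COLUMNS if c in df.columns]].to_csv(path, index=False)


def read_quant_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"replicate": str})


def write_mask_png(seg: SegmentationResult, path: str | Path) -> None:
    """Mask rendering: aggregate area black, remaining cell area mid-grey,
    background white."""
    import imageio.v3 as iio

    img = np.full(seg.cell_mask.shape, 255, dtype=np.uint8)
    img[seg.cell_mask] = 160
    img[seg.aggregate_mask] = 0
    iio.imwrite(Path(path), img)


def write_count_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_count_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_toxicity_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


def read_toxicity_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_lane_csv(profiles: Sequence[LaneProfile], path: str | Path) -> None:
    """Long-format lane CSV: condition, replicate, position_mm, signal."""
    rows = []
    for p in profiles:
        for x, y in zip(p.positions, p.signal):
            rows.append({"condition": p.condition, "replicate": p.replicate,
                         "position_mm": x, "signal": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lane_csv(path: str | Path) -> list[LaneProfile]:
    df = pd.read_csv(path)
    profiles = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=False):
        grp = grp.sort_values("position_mm")
        profiles.append(
            LaneProfile(positions=grp["position_mm"].to_numpy(),
                        signal=grp["signal"].to_numpy(),
                        condition=str(cond), replicate=str(rep))
        )
    return profiles
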