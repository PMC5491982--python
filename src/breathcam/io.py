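"""Frame and ground-truth file formats.

Thermal frames are zero-padded numbered 8-bit PNGs, depth frames CSV
matrices (metres), ground truth a JSON sidecar — all plain, inspectable
formats so recordings from real cameras can be dropped in the same shape.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .synthgen import DepthFrame, GroundTruth, ThermalFrame
from .types import ROI

__all__ = [
    "read_depth_frames",
    "read_ground_truth",
    "read_thermal_frames",
    "write_depth_frames",
    "write_ground_truth",
    "write_thermal_frames",
]


def write_thermal_frames(frames, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in frames:
        p = out / f"frame_{frame.index:06d}.png"
        Image.fromarray(frame.grey, mode="L").save(p)
        paths.append(p)
    return paths


def read_thermal_frames(in_dir: str | Path) -> list[ThermalFrame]:
    paths = sorted(Path(in_dir).glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {in_dir}")
    frames = []
    for i, p in enumerate(paths):
        grey = np.asarray(Image.open(p).convert("L"), dtype=np.uint8)
        frames.append(ThermalFrame(grey=grey, index=i))
    return frames


def write_depth_frames(frames, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in frames:
        p = out / f"depth_{frame.index:06d}.csv"
        np.savetxt(p, frame.values, fmt="%.6f", delimiter=",")
        paths.append(p)
    return paths


def read_depth_frames(in_dir: str | Path) -> list[DepthFrame]:
    paths = sorted(Path(in_dir).glob("depth_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no depth_*.csv files in {in_dir}")
    return [
        DepthFrame(values=np.loadtxt(p, delimiter=","), index=i)
        for i, p in enumerate(paths)
    ]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload: dict = {"breath_freq": truth.breath_freq}
    if truth.per_frame_mouth_roi is not None:
        payload["per_frame_mouth_roi"] = [r.to_list() for r in truth.per_frame_mouth_roi]
    if truth.per_frame_mean_mouth_temp is not None:
        payload["per_frame_mean_mouth_temp"] = np.asarray(
            truth.per_frame_mean_mouth_temp
        ).tolist()
    if truth.tmin_tmax_per_frame is not None:
        payload["tmin_tmax_per_frame"] = np.asarray(truth.tmin_tmax_per_frame).tolist()
    if truth.per_frame_chest_dist is not None:
        payload["per_frame_chest_dist"] = np.asarray(truth.per_frame_chest_dist).tolist()
    if truth.chest_roi is not None:
        payload["chest_roi"] = truth.chest_roi.to_list()
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        breath_freq=d["breath_freq"],
        per_frame_mouth_roi=(
            [ROI(*r) for r in d["per_frame_mouth_roi"]]
            if "per_frame_mouth_roi" in d
            else None
        ),
        per_frame_mean_mouth_temp=(
            np.asarray(d["per_frame_mean_mouth_temp"])
            if "per_frame_mean_mouth_temp" in d
            else None
        ),
        tmin_tmax_per_frame=(
            np.asarray(d["tmin_tmax_per_frame"]) if "tmin_tmax_per_frame" in d else None
        ),
        per_frame_chest_dist=(
            np.asarray(d["per_frame_chest_dist"]) if "per_frame_chest_dist" in d else None
        ),
        chest_roi=ROI(*d["chest_roi"]) if "chest_roi" in d else None,
    )
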