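"""Plain-text serialization of trajectories, detections and reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .infotheory import BitrateEstimate
from .preprocess import TranslocationTrajectory
from .simulate import RawTrajectory

__all__ = [
    "raw_to_frame",
    "raw_from_frame",
    "translocation_to_frame",
    "translocation_from_frame",
    "detections_to_frame",
    "write_bitrate_json",
    "read_bitrate_json",
]

RAW_COLUMNS = ["track_id", "time_min", "nuclear_ktr_mean", "field_mean"]


def raw_to_frame(trajectories: Sequence[RawTrajectory]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "track_id": t.track_id,
                "time_min": t.times,
                "nuclear_ktr_mean": t.nuclear_intensity,
                "field_mean": t.field_mean_intensity,
            }
        )
        for t in trajectories
    ]
    return pd.concat(frames, ignore_index=True)


def raw_from_frame(frame: pd.DataFrame) -> List[RawTrajectory]:
    missing = set(RAW_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory table lacks columns {sorted(missing)}")
    out = []
    for tid, grp in frame.groupby("track_id", sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            RawTrajectory(
                track_id=tid,
                times=grp["time_min"].to_numpy(),
                nuclear_intensity=grp["nuclear_ktr_mean"].to_numpy(),
                field_mean_intensity=grp["field_mean"].to_numpy(),
            )
        )
    return out


def translocation_to_frame(
    trajectories: Sequence[TranslocationTrajectory],
) -> pd.DataFrame:
    frames = [
        pd.DataFrame({"track_id": t.track_id, "time_min": t.times, "x": t.x})
        for t in trajectories
    ]
    return pd.concat(frames, ignore_index=True)


def translocation_from_frame(frame: pd.DataFrame) -> List[TranslocationTrajectory]:
    out = []
    for tid, grp in frame.groupby("track_id", sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            TranslocationTrajectory(
                track_id=tid,
                times=grp["time_min"].to_numpy(),
                x=grp["x"].to_numpy(),
            )
        )
    return out


def detections_to_frame(detections: Dict[int, np.ndarray]) -> pd.DataFrame:
    rows = [
        (tid, int(t)) for tid, times in detections.items() for t in np.asarray(times)
    ]
    return pd.DataFrame(rows, columns=["track_id", "detected_time_min"])


def binary_detections_to_frame(detections: Dict[int, Dict[int, int]]) -> pd.DataFrame:
    """Per-slot 0/1 detections (binary protocols) as a tidy table."""
    rows = [
        (tid, int(slot), int(flag))
        for tid, slots in detections.items()
        for slot, flag in sorted(slots.items())
    ]
    return pd.DataFrame(rows, columns=["track_id", "slot_time_min", "detected"])


def write_bitrate_json(path, estimate: BitrateEstimate) -> None:
    Path(path).write_text(json.dumps(estimate.to_dict(), indent=2) + "\n")


def read_bitrate_json(path) -> Dict:
    return json.loads(Path(path).read_text())
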