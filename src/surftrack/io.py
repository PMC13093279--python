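"""Readers and writers for the pipeline's CSV/JSON interchange formats.

All tables are plain CSV with documented column sets; transforms and
reports are JSON. Numeric round-trips are lossless at full double
precision (CSV floats are written with ``repr`` precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import Camera, CameraIntrinsics, CameraPose, GridPlate
from .geometry import RigidTransform
from .registration import LabeledCloud

__all__ = [
    "SchemaError",
    "DETECTION_COLUMNS",
    "CLOUD_COLUMNS",
    "SERIES_COLUMNS",
    "read_detections",
    "write_detections",
    "clouds_to_frame",
    "frame_to_clouds",
    "read_clouds",
    "write_clouds",
    "read_series_table",
    "write_series_table",
    "write_json",
    "read_json",
    "rig_to_dict",
    "rig_from_dict",
    "plates_to_dict",
    "plates_from_dict",
]

DETECTION_COLUMNS = ["frame_index", "time_s", "camera", "marker", "u_px", "v_px", "valid"]
CLOUD_COLUMNS = ["frame_index", "time_s", "marker", "x_mm", "y_mm", "z_mm", "role", "side", "valid"]
SERIES_COLUMNS = [
    "subject", "setup", "object", "time_s",
    "lr_mm", "ap_mm", "si_mm", "pitch_deg", "roll_deg", "yaw_deg", "valid",
]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _read_csv(path, required, what) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, required, what)
    return df


def read_detections(path) -> pd.DataFrame:
    return _read_csv(path, DETECTION_COLUMNS, "detections CSV")


def write_detections(df: pd.DataFrame, path) -> None:
    _check_columns(df, DETECTION_COLUMNS, "detections CSV")
    df.to_csv(path, index=False)


def clouds_to_frame(clouds: list[LabeledCloud]) -> pd.DataFrame:
    return pd.concat(
        [c.to_frame(frame_index=i) for i, c in enumerate(clouds)], ignore_index=True
    )


def frame_to_clouds(df: pd.DataFrame) -> list[LabeledCloud]:
    _check_columns(df, CLOUD_COLUMNS, "cloud CSV")
    clouds = []
    for _, g in df.groupby("frame_index", sort=True):
        clouds.append(
            LabeledCloud(
                labels=tuple(g["marker"]),
                points=g[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                roles=tuple(g["role"]),
                valid=g["valid"].to_numpy(bool),
                time_s=float(g["time_s"].iloc[0]),
                sides=tuple(g["side"]),
            )
        )
    return clouds


def read_clouds(path) -> list[LabeledCloud]:
    return frame_to_clouds(_read_csv(path, CLOUD_COLUMNS, "cloud CSV"))


def write_clouds(clouds: list[LabeledCloud], path) -> None:
    clouds_to_frame(clouds).to_csv(path, index=False)


def read_series_table(path) -> pd.DataFrame:
    return _read_csv(path, SERIES_COLUMNS, "series CSV")


def write_series_table(df: pd.DataFrame, path) -> None:
    _check_columns(df, SERIES_COLUMNS, "series CSV")
    df.to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, RigidTransform):
            return o.to_dict()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def rig_to_dict(rig: dict[str, Camera]) -> dict:
    out = {}
    for name, cam in rig.items():
        intr = cam.intrinsics
        out[name] = {
            "intrinsics": {
                k: getattr(intr, k)
                for k in ("fx", "fy", "cx", "cy", "skew", "k1", "k2", "k3",
                          "p1", "p2", "width", "height")
            },
            "pose": cam.pose.transform.to_dict(),
        }
    return out


def rig_from_dict(d: dict) -> dict[str, Camera]:
    rig = {}
    for name, c in d.items():
        intr = CameraIntrinsics(**c["intrinsics"])
        pose = CameraPose(RigidTransform.from_dict(c["pose"]), name=name)
        rig[name] = Camera(name, intr, pose)
    return rig


def plates_to_dict(plates: list[GridPlate]) -> list[dict]:
    return [
        {"rows": p.rows, "cols": p.cols, "spacing_mm": p.spacing_mm,
         "pose": p.pose.to_dict()}
        for p in plates
    ]


def plates_from_dict(items: list[dict]) -> list[GridPlate]:
    return [
        GridPlate(RigidTransform.from_dict(p["pose"]), rows=p["rows"],
                  cols=p["cols"], spacing_mm=p["spacing_mm"])
        for p in items
    ]
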