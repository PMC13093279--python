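"""Orchestration of the measurement stages into complete analyses.

The full chain mirrors the experiment: calibrate the rig on a grid plate,
verify accuracy on a held-out plate pose, detect markers, triangulate them
into labeled clouds, register every frame against the reference with ICP,
decompose the body / mask / relative transforms into 6-DoF displacement
series about the rotation-axis origin, and summarise (inter-fractional
mu / Sigma / sigma, BDT, pairwise setup statistics).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .camera import Camera, CameraPose, calibrate_extrinsics, select_camera_pair, triangulate_pair, verify_grid
from .detection import binarize, centroid_of_dark
from .geometry import AXIS_NAMES, RigidTransform, relative_transform, to_displacement
from .io import clouds_to_frame, write_json
from .metrics import (
    TOLERANCES,
    DisplacementSeries,
    bdt,
    displacement_series,
    interfraction_summary,
)
from .registration import LabeledCloud, TrackConfig, TrackResult, set_origin, track_sequence
from .simulate import (
    GridFixture,
    SceneConfig,
    grid_fixture,
    patch_boxes,
    render_frame_patches,
    simulate_interfraction,
    simulate_intrafraction,
)

__all__ = [
    "calibrate_rig",
    "detect_rendered_session",
    "triangulate_session",
    "track_session",
    "session_series",
    "run_demo",
]


# ---------------------------------------------------------------------------
# calibration stage


def calibrate_rig(
    fixture: GridFixture,
    init_poses: dict[str, CameraPose] | None = None,
) -> tuple[dict[str, Camera], dict[str, float]]:
    """Calibrate every camera's extrinsics from a grid fixture.

    ``init_poses`` defaults to the rig's nominal design poses. Returns the
    calibrated rig and per-camera RMS reprojection errors (pixels).
    """
    calibrated, rms = {}, {}
    for name, cam in fixture.rig.items():
        obj, img = fixture.calib_observations(name)
        init = init_poses[name] if init_poses else cam.pose
        pose, err = calibrate_extrinsics(cam.intrinsics, obj, img, init)
        calibrated[name] = Camera(name, cam.intrinsics, pose)
        rms[name] = err
    return calibrated, rms


# ---------------------------------------------------------------------------
# detection stage (rendered-image path)


def detect_rendered_session(record, patch_px: int = 96) -> pd.DataFrame:
    """Render every marker patch of a simulated session and detect centroids.

    This is the image-based detection path: the simulator renders the dark
    marker discs into their static patch boxes and the detection stage runs
    binarisation + dark-pixel centroiding, producing the same detections
    table as the analytic path.
    """
    boxes = patch_boxes(record.rig, record.reference, patch_px=patch_px)
    rows = []
    for t, cloud in enumerate(record.clouds):
        for cam_name in record.rig:
            patches = render_frame_patches(record.rig, cloud, boxes, cam_name)
            for lab, patch in patches.items():
                det = centroid_of_dark(binarize(patch), patch.offset, label=lab, camera=cam_name)
                rows.append((
                    t, float(record.times[t]), cam_name, lab,
                    det.u_px, det.v_px, det.valid,
                ))
    return pd.DataFrame(
        rows, columns=["frame_index", "time_s", "camera", "marker", "u_px", "v_px", "valid"]
    )


# ---------------------------------------------------------------------------
# triangulation stage


def triangulate_session(
    detections: pd.DataFrame,
    rig: dict[str, Camera],
    layout: LabeledCloud,
) -> list[LabeledCloud]:
    """Triangulate a detections table into per-frame labeled clouds.

    The camera pair per marker follows the side rule (front+left for
    left-side markers, front+right for right-side, lateral fallback).
    Markers seen by fewer than two cameras are flagged invalid.
    """
    from .camera import triangulate_points

    side_of = dict(zip(layout.labels, layout.sides))
    clouds = []
    for frame_idx, g in detections.groupby("frame_index", sort=True):
        time_s = float(g["time_s"].iloc[0])
        wide = g.pivot(index="marker", columns="camera", values=["u_px", "v_px", "valid"])
        pts = np.array(layout.points, float)
        valid = np.zeros(len(layout.labels), bool)
        by_pair: dict[tuple, list[int]] = {}
        for i, lab in enumerate(layout.labels):
            if lab not in wide.index:
                continue
            avail = {
                cam: bool(wide.at[lab, ("valid", cam)])
                for cam in rig
                if (("valid", cam) in wide.columns
                    and pd.notna(wide.at[lab, ("valid", cam)]))
            }
            pair = select_camera_pair(side_of[lab], avail)
            if pair is None:
                continue
            by_pair.setdefault(pair, []).append(i)
        for (a, b), idx in by_pair.items():
            labs = [layout.labels[i] for i in idx]
            px_a = wide.loc[labs, [("u_px", a), ("v_px", a)]].to_numpy(float)
            px_b = wide.loc[labs, [("u_px", b), ("v_px", b)]].to_numpy(float)
            tri, _ = triangulate_points(
                (rig[a].intrinsics, rig[a].pose),
                (rig[b].intrinsics, rig[b].pose),
                px_a, px_b,
            )
            pts[idx] = tri
            valid[idx] = True
        clouds.append(layout.with_points(pts, valid=valid, time_s=time_s))
    return clouds


# ---------------------------------------------------------------------------
# tracking + displacement stages


def track_session(
    clouds: list[LabeledCloud],
    setup_type: str,
    cfg: TrackConfig | None = None,
) -> tuple[TrackResult, np.ndarray]:
    """Register a session against its reference frame; returns (track, origin)."""
    cfg = cfg or TrackConfig(setup_type=setup_type)
    origin = set_origin(clouds[0], setup_type)
    return track_sequence(clouds, cfg), origin


def session_series(
    track: TrackResult,
    origin: np.ndarray,
    subject: str = "",
    setup: str = "",
) -> dict[str, DisplacementSeries]:
    """Body, mask and body-relative-to-mask displacement series of a session."""
    relative = [
        relative_transform(b, m) if (b is not None and m is not None) else None
        for b, m in zip(track.body, track.mask)
    ]
    out = {}
    for name, transforms in (("body", track.body), ("mask", track.mask), ("relative", relative)):
        out[name] = displacement_series(
            transforms, track.times, origin,
            subject=subject, setup=setup, object_name=name,
        )
    return out


# ---------------------------------------------------------------------------
# demonstration run


def _config_hash(cfg: SceneConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_demo(seed: int, out_dir, n_subjects: int = 15) -> dict:
    """End-to-end demonstration on synthetic data; writes the session report.

    Runs grid verification, one intra-fractional abdominal session (track,
    displacement series, BDT) and an inter-fractional ensemble
    (mu / Sigma / sigma summary), writing deterministic numeric tables under
    ``out_dir``. Returns the report dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = SceneConfig(seed=int(seed))

    # grid accuracy (held-out plate pose, manual-detection-level pixel noise)
    fixture = grid_fixture(cfg, noise_px=0.5)
    rig_cal, rms = calibrate_rig(fixture)
    grid_report = verify_grid(rig_cal, fixture.verify_plate, fixture.verify_detections())
    grid_df = grid_report.to_frame()
    grid_df.to_csv(out_dir / "grid_accuracy.csv", index=False)

    # intra-fractional session
    record = simulate_intrafraction(cfg)
    clouds = triangulate_session(record.detections, record.rig, record.reference)
    track, origin = track_session(clouds, cfg.layout)
    series = session_series(track, origin, subject="demo", setup=cfg.layout)
    series_df = pd.concat([s.to_frame() for s in series.values()], ignore_index=True)
    series_df.to_csv(out_dir / "displacement_series.csv", index=False)
    bdt_res = bdt(series["body"], TOLERANCES[cfg.layout])

    # inter-fractional ensemble (truth offsets measured per repetition)
    inter = simulate_interfraction(cfg, n_subjects=n_subjects, n_reps=5)
    summary = interfraction_summary(inter.offset_table())

    report = {
        "provenance": {
            "seed": int(seed),
            "config_hash": _config_hash(cfg),
            "version": __version__,
        },
        "grid_accuracy": grid_df.to_dict(orient="records"),
        "calibration_rms_px": rms,
        "bdt": {
            "total_min": bdt_res.total_min,
            "per_axis_min": bdt_res.per_axis_min,
            "convention": bdt_res.convention,
        },
        "interfraction_summary": {
            "per_axis": {ax: list(v) for ax, v in summary.per_axis.items()},
            "threed": list(summary.threed),
            "overall_3d": list(summary.overall_3d),
            "n_subjects": summary.n_subjects,
        },
        "body_displacement_at_end_mm_deg": dict(
            zip(AXIS_NAMES, series["body"].values[-1].round(12))
        ),
        "counts": {
            "frames": len(clouds),
            "unregistered_frames": int(track.unregistered.sum()),
            "detections": int(len(record.detections)),
            "invalid_detections": int((~record.detections["valid"]).sum()),
        },
    }
    write_json(report, out_dir / "report.json")
    return report
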