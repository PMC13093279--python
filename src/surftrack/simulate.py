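"""Synthetic scene and motion simulator.

Generates every input the measurement pipeline consumes — camera rig, marker
layouts, ground-truth motion, 2D detections, calibration grid fixtures and
rendered marker patches — with fully known parameters, so that each pipeline
stage can be tested by simulate-then-recover.

The emulated study conditions:

* a three-camera rig (front / left / right) of 5496 x 3672-pixel cameras
  with 25-mm lenses, ~1.5 m from the chair's vertical rotation axis;
* 26 labeled 5-mm markers on body and thermoplastic mask (abdominal or
  head-and-neck layout; the true marker geometry is unpublished, so the
  coordinates here are plausible defaults, documented in one place);
* per-subject inter-fractional offsets with systematic and random
  components (5 repetitions per subject);
* intra-fractional saturating drift ``A (1 - e^(-t/tau))``, largest within
  the first ~5 min and directed anterior / inferior by default;
* quasi-periodic respiratory displacement of the abdominal surrogate
  markers (a ~4-s sinusoid deliberately aliased by the 5-s frame cadence);
* small mask-relative-to-body drift, near-static thigh markers;
* 4% random marker dropout and sub-pixel detection noise.

All randomness flows from one integer seed through named sub-streams, so a
stage can be re-run independently and bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .camera import Camera, CameraIntrinsics, CameraPose, GridPlate, project
from .detection import ImagePatch
from .geometry import Displacement6D, RigidTransform, from_displacement, to_displacement
from .registration import DEFAULT_AXIS_AP, DEFAULT_AXIS_LR, LabeledCloud, set_origin

__all__ = [
    "MotionModel",
    "SceneConfig",
    "IntrafractionRecord",
    "InterfractionRecord",
    "GridFixture",
    "make_rig",
    "make_layout",
    "simulate_intrafraction",
    "simulate_interfraction",
    "grid_fixture",
    "patch_boxes",
    "render_patch",
    "render_frame_patches",
]

AXIS_AIM_Z = {"abdominal": 1070.0, "hn": 1500.0}


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible random stream keyed by ``name``."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


@dataclass(frozen=True)
class MotionModel:
    """Parameters of the simulated motion, in mm / degrees / seconds.

    Intra-fractional drift is the saturating curve ``A (1 - e^(-t/tau))``
    per axis in the order (lr, ap, si, pitch, roll, yaw); the default drives
    the body anterior (+AP) and inferior (-SI) with a 150-s time constant,
    so most of the drift happens within the first five minutes. Respiration
    is a zero-mean sinusoid added to the respiratory surrogate markers only.
    Inter-fractional offsets are drawn per subject (systematic) and per
    repetition (random).
    """

    drift_amplitude: tuple = (0.2, 1.5, -1.5, 0.3, 0.1, 0.1)
    drift_tau_s: float = 150.0
    resp_amplitude_mm: tuple = (0.0, 1.5, 0.3)
    resp_period_s: float = 4.0
    resp_phase_rad: float = 0.0
    mask_drift_amplitude: tuple = (0.05, 0.3, -0.2, 0.05, 0.02, 0.02)
    mask_drift_tau_s: float = 300.0
    thigh_amplitude_mm: float = 0.3
    thigh_period_s: float = 600.0
    inter_systematic_trans_mm: float = 2.0
    inter_random_trans_mm: float = 1.5
    inter_systematic_rot_deg: float = 0.8
    inter_random_rot_deg: float = 0.5

    def drift(self, t: float) -> np.ndarray:
        amp = np.asarray(self.drift_amplitude, float)
        return amp * (1.0 - np.exp(-float(t) / self.drift_tau_s))

    def mask_drift(self, t) -> np.ndarray:
        amp = np.asarray(self.mask_drift_amplitude, float)
        return amp * (1.0 - np.exp(-float(t) / self.mask_drift_tau_s))

    def respiration(self, t) -> np.ndarray:
        amp = np.asarray(self.resp_amplitude_mm, float)
        return amp * np.sin(2 * np.pi * float(t) / self.resp_period_s + self.resp_phase_rad)


@dataclass(frozen=True)
class SceneConfig:
    """Full configuration of a simulated session."""

    layout: str = "abdominal"              # abdominal | hn
    camera_distance_mm: float = 1500.0
    focal_mm: float = 25.0
    pixel_pitch_mm: float = 0.0024
    image_width: int = 5496
    image_height: int = 3672
    pixel_noise_px: float = 0.2
    dropout: float = 0.04
    duration_s: float = 1200.0
    cadence_s: float = 5.0
    seed: int = 0
    axis_lr: float = DEFAULT_AXIS_LR
    axis_ap: float = DEFAULT_AXIS_AP
    motion: MotionModel = field(default_factory=MotionModel)

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout probability must be in [0, 1]")
        if self.layout not in AXIS_AIM_Z:
            raise ValueError(f"layout must be one of {sorted(AXIS_AIM_Z)}")

    @property
    def aim_z(self) -> float:
        return AXIS_AIM_Z[self.layout]

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + self.cadence_s / 2, self.cadence_s)


# ---------------------------------------------------------------------------
# rig


def _look_at(position: np.ndarray, target: np.ndarray, name: str) -> CameraPose:
    """World-to-camera pose with +z toward ``target`` and image-v downward."""
    position = np.asarray(position, float)
    fwd = target - position
    norm = np.linalg.norm(fwd)
    if norm < 1e-9:
        raise ValueError("camera placed at its target")
    fwd = fwd / norm
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(fwd, up)
    right /= np.linalg.norm(right)
    down = np.cross(fwd, right)
    rot = np.stack([right, down, fwd])
    return CameraPose(RigidTransform(rot, -rot @ position), name=name)


def make_rig(cfg: SceneConfig) -> dict[str, Camera]:
    """Three calibrated cameras aimed at the marker volume.

    The front camera sits anterior of the subject looking posterior; the
    left and right cameras sit obliquely on the patient's left/right
    (75 degrees of azimuth off the front direction), so that the lateral
    pair still subtends a usable triangulation angle and both lateral
    cameras see the anterior marker surface. All three share the same
    intrinsics model.
    """
    intr = CameraIntrinsics.from_lens(
        cfg.focal_mm, cfg.pixel_pitch_mm, cfg.image_width, cfg.image_height
    )
    target = np.array([cfg.axis_lr, cfg.axis_ap, cfg.aim_z])
    d = cfg.camera_distance_mm
    az = np.deg2rad(75.0)
    positions = {
        "front": target + np.array([0.0, d, 0.0]),
        "left": target + d * np.array([np.sin(az), np.cos(az), 0.0]),
        "right": target + d * np.array([-np.sin(az), np.cos(az), 0.0]),
    }
    centers = list(positions.values())
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < 1e-6:
                raise ValueError("coincident camera centres")
    return {
        name: Camera(name, intr, _look_at(pos, target, name))
        for name, pos in positions.items()
    }


# ---------------------------------------------------------------------------
# marker layouts


def _side_of(x: float, margin: float = 15.0) -> str:
    if x > margin:
        return "left"
    if x < -margin:
        return "right"
    return "central"


def make_layout(
    setup: str,
    axis_lr: float = DEFAULT_AXIS_LR,
    axis_ap: float = DEFAULT_AXIS_AP,
) -> LabeledCloud:
    """Reference marker layout (26 labeled markers) for one setup type.

    Abdominal: A1-A9 respiratory surrogates on a 3 x 3 grid of the anterior
    abdomen (elliptic-cylinder torso), A10-A11 on the thighs, M1-M15 on the
    anterior thermoplastic-mask shell 8 mm proud of the skin. Head-and-neck:
    H1-H10 rigid head markers through the mask holes on an ellipsoidal head,
    M1-M16 on the mask shell. The published figures do not print marker
    coordinates; these are plausible defaults with >= 20 mm inter-marker
    spacing (a nearest-neighbour-ICP safety margin).
    """
    cx, cy = axis_lr, axis_ap
    labels, points, roles = [], [], []
    if setup == "abdominal":
        a, b = 170.0, 110.0               # torso semi-axes, LR x AP
        for zi, z in enumerate((1240.0, 1150.0, 1060.0)):
            for ti, theta in enumerate((-40.0, 0.0, 40.0)):
                th = np.deg2rad(theta)
                labels.append(f"A{zi * 3 + ti + 1}")
                points.append([cx + a * np.sin(th), cy + b * np.cos(th), z])
                roles.append("body_respiratory")
        for lab, x in (("A10", 80.0), ("A11", -80.0)):
            labels.append(lab)
            points.append([cx + x, cy + 200.0, 900.0])
            roles.append("thigh")
        am, bm = a + 8.0, b + 8.0         # mask shell
        k = 0
        for z in (1195.0, 1105.0, 1015.0):
            for theta in (-60.0, -30.0, 0.0, 30.0, 60.0):
                th = np.deg2rad(theta)
                k += 1
                labels.append(f"M{k}")
                points.append([cx + am * np.sin(th), cy + bm * np.cos(th), z])
                roles.append("mask")
    elif setup == "hn":
        hc = np.array([cx, cy, 1500.0])
        ax, by, cz = 80.0, 100.0, 110.0   # head semi-axes LR / AP / SI
        def on_head(theta, phi, grow=0.0):
            th, ph = np.deg2rad(theta), np.deg2rad(phi)
            return hc + np.array([
                (ax + grow) * np.sin(th) * np.cos(ph),
                (by + grow) * np.cos(th) * np.cos(ph),
                (cz + grow) * np.sin(ph),
            ])
        k = 0
        for phi in (30.0, 0.0, -30.0):
            for theta in (-40.0, 0.0, 40.0):
                k += 1
                labels.append(f"H{k}")
                points.append(on_head(theta, phi))
                roles.append("body_rigid")
        labels.append("H10")
        points.append(on_head(0.0, 60.0))
        roles.append("body_rigid")
        k = 0
        for phi in (45.0, 15.0, -15.0, -45.0):
            for theta in (-60.0, -20.0, 20.0, 60.0):
                k += 1
                labels.append(f"M{k}")
                points.append(on_head(theta, phi, grow=8.0))
                roles.append("mask")
    else:
        raise ValueError(f"unknown setup {setup!r}")
    # H1 (hn) / A2 (abdominal) are the SI anchors used for the origin rule
    pts = np.asarray(points)
    sides = tuple(_side_of(p[0] - cx) for p in pts)
    return LabeledCloud(
        labels=tuple(labels),
        points=pts,
        roles=tuple(roles),
        valid=np.ones(len(labels), bool),
        time_s=0.0,
        sides=sides,
    )


# ---------------------------------------------------------------------------
# intra-fractional simulation


@dataclass
class IntrafractionRecord:
    """Simulated session with ground truth stored alongside the observations."""

    config: SceneConfig
    rig: dict
    reference: LabeledCloud
    origin: np.ndarray
    times: np.ndarray
    body_transforms: list          # truth, reference -> frame
    mask_transforms: list
    body_displacement: np.ndarray  # (T, 6) truth about origin
    mask_displacement: np.ndarray
    clouds: list                   # LabeledCloud per frame (truth 3D, with dropout flags)
    detections: pd.DataFrame


def _project_detections(
    rig: dict,
    clouds: list[LabeledCloud],
    times: np.ndarray,
    noise_px: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for t, cloud in enumerate(clouds):
        for cam in rig.values():
            for i, lab in enumerate(cloud.labels):
                ok = bool(cloud.valid[i])
                u = v = np.nan
                if ok:
                    try:
                        px = project(cam.intrinsics, cam.pose, cloud.points[i])
                    except ValueError:
                        ok = False
                    else:
                        if noise_px > 0:
                            px = px + rng.normal(0.0, noise_px, 2)
                        ok = bool(cam.intrinsics.in_bounds(px)[0])
                        u, v = float(px[0]), float(px[1])
                rows.append((t, float(times[t]), cam.name, lab, u, v, ok))
    return pd.DataFrame(
        rows, columns=["frame_index", "time_s", "camera", "marker", "u_px", "v_px", "valid"]
    )


def simulate_intrafraction(cfg: SceneConfig, with_detections: bool = True) -> IntrafractionRecord:
    """Simulate a 20-min monitoring session at 5-s cadence.

    The body follows the rigid drift trajectory of ``cfg.motion`` about the
    reporting origin; the mask follows the body composed with a small extra
    mask-relative drift; respiratory markers breathe additively; thigh
    markers stay near-static. Dropout and pixel noise are applied to the
    emitted detections (never to the stored ground truth). Frame 0 is the
    clean reference image.
    """
    rig = make_rig(cfg)
    reference = make_layout(cfg.layout, cfg.axis_lr, cfg.axis_ap)
    origin = set_origin(reference, cfg.layout, cfg.axis_lr, cfg.axis_ap)
    times = cfg.times()
    motion = cfg.motion
    rng_drop = _stream(cfg.seed, "intrafraction/dropout")
    rng_px = _stream(cfg.seed, "intrafraction/pixel_noise")
    rng_thigh = _stream(cfg.seed, "intrafraction/thigh")

    thigh_idx = np.nonzero(reference.role_mask("thigh"))[0]
    thigh_dirs = rng_thigh.normal(size=(len(thigh_idx), 3))
    thigh_dirs /= np.linalg.norm(thigh_dirs, axis=1, keepdims=True)
    thigh_phase = rng_thigh.uniform(0, 2 * np.pi, len(thigh_idx))

    body_mask_sel = reference.role_mask(("body_rigid", "body_respiratory"))
    resp_sel = reference.role_mask("body_respiratory")
    mask_sel = reference.role_mask("mask")

    body_transforms, mask_transforms, clouds = [], [], []
    body_disp = np.zeros((len(times), 6))
    mask_disp = np.zeros((len(times), 6))
    for t_idx, t in enumerate(times):
        d_body = motion.drift(t)
        m_body = from_displacement(Displacement6D.from_array(d_body), origin)
        m_rel = from_displacement(Displacement6D.from_array(motion.mask_drift(t)), origin)
        m_mask = m_rel.compose(m_body)
        body_transforms.append(m_body)
        mask_transforms.append(m_mask)
        body_disp[t_idx] = d_body
        mask_disp[t_idx] = to_displacement(m_mask, origin).as_array()

        pts = reference.points.copy()
        pts[body_mask_sel] = m_body.apply(reference.points[body_mask_sel])
        pts[mask_sel] = m_mask.apply(reference.points[mask_sel])
        pts[resp_sel] += motion.respiration(t)
        for j, i in enumerate(thigh_idx):
            amp = motion.thigh_amplitude_mm
            pts[i] = reference.points[i] + thigh_dirs[j] * amp * np.sin(
                2 * np.pi * t / motion.thigh_period_s + thigh_phase[j]
            )
        valid = reference.valid.copy()
        if t_idx > 0 and cfg.dropout > 0:
            valid &= rng_drop.random(len(valid)) >= cfg.dropout
        clouds.append(reference.with_points(pts, valid=valid, time_s=float(t)))

    detections = (
        _project_detections(rig, clouds, times, cfg.pixel_noise_px, rng_px)
        if with_detections
        else pd.DataFrame()
    )
    return IntrafractionRecord(
        config=cfg,
        rig=rig,
        reference=reference,
        origin=origin,
        times=times,
        body_transforms=body_transforms,
        mask_transforms=mask_transforms,
        body_displacement=body_disp,
        mask_displacement=mask_disp,
        clouds=clouds,
        detections=detections,
    )


# ---------------------------------------------------------------------------
# inter-fractional simulation


@dataclass
class InterfractionRecord:
    config: SceneConfig
    n_subjects: int
    n_reps: int
    offsets: np.ndarray        # (S, R, 6) truth per-repetition displacement
    systematic: np.ndarray     # (S, 6) truth per-subject systematic component
    origin: np.ndarray
    clouds: dict | None        # (subject, rep) -> LabeledCloud, optional

    def offset_table(self) -> pd.DataFrame:
        """Truth per-repetition displacements as a tidy table."""
        from .geometry import AXIS_NAMES
        rows = []
        for s in range(self.n_subjects):
            for r in range(self.n_reps):
                rows.append({"subject": f"S{s:03d}", "rep": r,
                             **dict(zip(AXIS_NAMES, self.offsets[s, r]))})
        return pd.DataFrame(rows)


def simulate_interfraction(
    cfg: SceneConfig,
    n_subjects: int,
    n_reps: int = 5,
    make_clouds: bool = False,
) -> InterfractionRecord:
    """Simulate repeated setups: systematic per subject, random per repetition.

    Each subject draws one systematic offset ~ N(0, Sigma*) per axis; each
    of the ``n_reps`` repetitions adds an independent random offset
    ~ N(0, sigma*). With ``make_clouds`` the per-repetition marker clouds
    (whole body + mask moved rigidly by the offset) are emitted as well.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    m = cfg.motion
    rng = _stream(cfg.seed, "interfraction/offsets")
    sig_sys = np.array([m.inter_systematic_trans_mm] * 3 + [m.inter_systematic_rot_deg] * 3)
    sig_rand = np.array([m.inter_random_trans_mm] * 3 + [m.inter_random_rot_deg] * 3)
    systematic = rng.normal(0.0, 1.0, (n_subjects, 6)) * sig_sys
    random = rng.normal(0.0, 1.0, (n_subjects, n_reps, 6)) * sig_rand
    offsets = systematic[:, None, :] + random

    reference = make_layout(cfg.layout, cfg.axis_lr, cfg.axis_ap)
    origin = set_origin(reference, cfg.layout, cfg.axis_lr, cfg.axis_ap)
    clouds = None
    if make_clouds:
        clouds = {}
        for s in range(n_subjects):
            for r in range(n_reps):
                tr = from_displacement(Displacement6D.from_array(offsets[s, r]), origin)
                clouds[(s, r)] = reference.with_points(tr.apply(reference.points))
    return InterfractionRecord(
        config=cfg,
        n_subjects=n_subjects,
        n_reps=n_reps,
        offsets=offsets,
        systematic=systematic,
        origin=origin,
        clouds=clouds,
    )


# ---------------------------------------------------------------------------
# grid-plate fixture


@dataclass
class GridFixture:
    rig: dict
    calib_plates: list            # GridPlate per calibration pose
    verify_plate: GridPlate
    detections: pd.DataFrame      # pose_id, camera, row, col, u_px, v_px, valid
    noise_px: float

    def calib_observations(self, camera: str) -> tuple[np.ndarray, np.ndarray]:
        """(object_points, image_points) of all calibration poses for one camera."""
        obj, img = [], []
        det = self.detections
        for pid, plate in enumerate(self.calib_plates):
            d = det[(det["pose_id"] == pid) & (det["camera"] == camera) & det["valid"]]
            world = plate.world_points().reshape(plate.rows, plate.cols, 3)
            obj.append(world[d["row"].to_numpy(), d["col"].to_numpy()])
            img.append(d[["u_px", "v_px"]].to_numpy())
        return np.concatenate(obj), np.concatenate(img)

    def verify_detections(self) -> pd.DataFrame:
        return self.detections[self.detections["pose_id"] == len(self.calib_plates)]


_CALIB_POSE_PARAMS = [
    # (yaw_deg about SI, tilt_deg about LR, dx, dy, dz) of the plate
    (0.0, 0.0, 0.0, 0.0, 0.0),
    (20.0, 0.0, -30.0, 20.0, 10.0),
    (-20.0, 0.0, 30.0, -20.0, -10.0),
    (0.0, 15.0, 0.0, 40.0, 30.0),
    (10.0, -15.0, -40.0, -30.0, -20.0),
    (-10.0, 10.0, 40.0, 10.0, 20.0),
]
_VERIFY_POSE_PARAMS = (5.0, 5.0, 15.0, -10.0, 15.0)


def _plate_pose(cfg: SceneConfig, params) -> RigidTransform:
    yaw, tilt, dx, dy, dz = params
    base = np.array([cfg.axis_lr, cfg.axis_ap + 50.0, cfg.aim_z])
    disp = Displacement6D(0.0, 0.0, 0.0, tilt, 0.0, yaw)
    rot = from_displacement(disp, (0.0, 0.0, 0.0)).rotation
    return RigidTransform(rot, base + np.array([dx, dy, dz]))


def grid_fixture(
    cfg: SceneConfig,
    n_calib: int = 6,
    noise_px: float = 0.0,
    rig: dict | None = None,
) -> GridFixture:
    """Calibration-grid acquisition: ``n_calib`` plate poses plus one held out.

    The 41 x 58 plate (5-mm spacing, 2378 points) is placed near the
    rotation axis at predefined tilted poses; detections are the projected
    grid points per camera with optional Gaussian pixel noise. The true
    camera poses live in ``rig`` for recovery checks.
    """
    if n_calib > len(_CALIB_POSE_PARAMS):
        raise ValueError(f"at most {len(_CALIB_POSE_PARAMS)} predefined calibration poses")
    rig = rig if rig is not None else make_rig(cfg)
    rng = _stream(cfg.seed, "grid/pixel_noise")
    plates = [GridPlate(_plate_pose(cfg, p)) for p in _CALIB_POSE_PARAMS[:n_calib]]
    verify = GridPlate(_plate_pose(cfg, _VERIFY_POSE_PARAMS))
    rows = []
    for pid, plate in enumerate([*plates, verify]):
        world = plate.world_points()
        idx = plate.point_index()
        for cam in rig.values():
            px = project(cam.intrinsics, cam.pose, world)
            if noise_px > 0:
                px = px + rng.normal(0.0, noise_px, px.shape)
            ok = cam.intrinsics.in_bounds(px)
            for i in range(len(world)):
                rows.append((
                    pid, cam.name, int(idx["row"][i]), int(idx["col"][i]),
                    float(px[i, 0]), float(px[i, 1]), bool(ok[i]),
                ))
    det = pd.DataFrame(rows, columns=["pose_id", "camera", "row", "col", "u_px", "v_px", "valid"])
    return GridFixture(rig=rig, calib_plates=plates, verify_plate=verify,
                       detections=det, noise_px=noise_px)


# ---------------------------------------------------------------------------
# patch rendering (for the image-based detection path)


def patch_boxes(
    rig: dict,
    reference: LabeledCloud,
    patch_px: int = 96,
) -> dict[str, dict[str, tuple[int, int, int, int]]]:
    """Static per-camera patch boxes centred on the reference projections."""
    out: dict[str, dict] = {}
    half = patch_px // 2
    for cam in rig.values():
        boxes = {}
        for i, lab in enumerate(reference.labels):
            try:
                px = project(cam.intrinsics, cam.pose, reference.points[i])
            except ValueError:
                continue
            u0 = int(round(px[0])) - half
            v0 = int(round(px[1])) - half
            if (u0 < 0 or v0 < 0 or u0 + patch_px > cam.intrinsics.width
                    or v0 + patch_px > cam.intrinsics.height):
                continue
            boxes[lab] = (u0, v0, patch_px, patch_px)
        out[cam.name] = boxes
    return out


def render_patch(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius_px: float,
    foreground: int = 20,
    background: int = 220,
) -> np.ndarray:
    """Render one anti-aliased dark disc into an 8-bit patch.

    Pixel coverage is approximated by a 1-px linear ramp of the signed
    distance to the circle, so binarisation at the mid-level recovers
    exactly the pixels whose centres lie inside the circle.
    """
    h, w = shape
    vv, uu = np.mgrid[0:h, 0:w]
    dist = np.hypot(uu - center[0], vv - center[1])
    coverage = np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    img = background + (foreground - background) * coverage
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_frame_patches(
    rig: dict,
    cloud: LabeledCloud,
    boxes: dict[str, dict[str, tuple[int, int, int, int]]],
    camera: str,
    marker_diameter_mm: float = 5.0,
) -> dict[str, ImagePatch]:
    """Render the patches of one camera for one frame (valid markers only).

    Markers outside their patch box render as pure background, mimicking a
    covered or displaced marker.
    """
    cam = rig[camera]
    out = {}
    for lab, box in boxes[camera].items():
        i = cloud.index(lab)
        u0, v0, w, h = box
        if not cloud.valid[i]:
            out[lab] = ImagePatch(np.full((h, w), 220, np.uint8), (u0, v0), lab, camera)
            continue
        p_cam = cam.pose.transform.apply(cloud.points[i])
        px = project(cam.intrinsics, cam.pose, cloud.points[i])
        radius_px = (marker_diameter_mm / 2.0) * cam.intrinsics.fx / p_cam[2]
        patch = render_patch((h, w), (px[0] - u0, px[1] - v0), radius_px)
        out[lab] = ImagePatch(patch, (float(u0), float(v0)), lab, camera)
    return out
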