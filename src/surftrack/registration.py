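"""Rigid point-cloud registration and per-frame tracking of body and mask.

The measurement registers labeled marker clouds against the reference image
(frame 0 of a session) with an iterative-closest-point (ICP) scheme whose
inner step is the closed-form Kabsch fit. Abdominal body markers (A1-A9)
move non-rigidly with respiration and are therefore temporally smoothed
over five frames before registration; thigh markers (A10, A11) are reported
individually and excluded from the body fit.

The recovered :class:`~surftrack.geometry.RigidTransform` maps reference
coordinates to current coordinates, so its displacement decomposition reads
as "how far the object moved since the reference image".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import RigidTransform

__all__ = [
    "ROLES",
    "LabeledCloud",
    "ICPConfig",
    "ICPResult",
    "TrackConfig",
    "TrackResult",
    "RegistrationError",
    "kabsch",
    "icp",
    "smooth_series",
    "set_origin",
    "track_sequence",
]

ROLES = ("mask", "body_rigid", "body_respiratory", "thigh")
BODY_ROLES = ("body_rigid", "body_respiratory")

#: LR/AP position of the chair's vertical rotation axis (mm): the vertical
#: laser planes intersect 15 cm anterior to the backrest plane (y = 0).
DEFAULT_AXIS_LR = 0.0
DEFAULT_AXIS_AP = 150.0

ANCHOR_MARKER = {"abdominal": "A2", "hn": "H1"}


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LabeledCloud:
    """Labeled 3D marker positions with role tags and validity flags."""

    labels: tuple[str, ...]
    points: np.ndarray          # (N, 3) mm
    roles: tuple[str, ...]      # one of ROLES per label
    valid: np.ndarray           # (N,) bool
    time_s: float = 0.0
    sides: tuple[str, ...] = ()  # left | right | central, for camera-pair choice

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float).reshape(len(self.labels), 3)
        val = np.asarray(self.valid, bool).reshape(len(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("marker labels must be unique")
        if any(r not in ROLES for r in self.roles):
            raise ValueError(f"roles must be in {ROLES}")
        if np.any(~np.isfinite(pts[val])):
            raise ValueError("valid points must be finite")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "roles", tuple(self.roles))
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "valid", val)
        if not self.sides:
            object.__setattr__(self, "sides", tuple("central" for _ in self.labels))

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, label: str) -> np.ndarray:
        return self.points[self.index(label)]

    def role_mask(self, roles) -> np.ndarray:
        roles = {roles} if isinstance(roles, str) else set(roles)
        return np.array([r in roles for r in self.roles], bool)

    def with_points(self, points: np.ndarray, valid=None, time_s=None) -> "LabeledCloud":
        return LabeledCloud(
            self.labels,
            points,
            self.roles,
            self.valid if valid is None else valid,
            self.time_s if time_s is None else time_s,
            self.sides,
        )

    def to_frame(self, frame_index: int = 0) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_index": frame_index,
            "time_s": self.time_s,
            "marker": self.labels,
            "x_mm": self.points[:, 0],
            "y_mm": self.points[:, 1],
            "z_mm": self.points[:, 2],
            "role": self.roles,
            "side": self.sides,
            "valid": self.valid,
        })


@dataclass(frozen=True)
class ICPConfig:
    max_iterations: int = 50
    tolerance_mm: float = 1e-6        # convergence threshold on the RMS change
    correspondence: str = "nearest"   # "nearest" | "labeled"
    init: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if self.tolerance_mm <= 0 or self.max_iterations < 1:
            raise ValueError("tolerance must be > 0 and max_iterations >= 1")
        if self.correspondence not in ("nearest", "labeled"):
            raise ValueError("correspondence must be 'nearest' or 'labeled'")


@dataclass(frozen=True)
class ICPResult:
    transform: RigidTransform
    rms_mm: float
    iterations: int
    converged: bool
    rms_history: tuple[float, ...]
    n_points: int


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit ``target ~ R @ source + t``.

    Uses the SVD of the cross-covariance; a reflection is never returned
    (det R = +1 enforced). Requires >= 3 non-collinear point pairs.
    """
    src = np.asarray(source, float).reshape(-1, 3)
    tgt = np.asarray(target, float).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise ValueError("source and target must have equal shapes")
    if src.shape[0] < 3:
        raise RegistrationError(f"need >= 3 point pairs, got {src.shape[0]}")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    h = (src - cs).T @ (tgt - ct)
    if np.linalg.matrix_rank(h, tol=1e-9) < 2:
        raise RegistrationError("degenerate (collinear) point configuration")
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, ct - rot @ cs)


def _rms(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def icp(
    source: LabeledCloud,
    target: LabeledCloud,
    cfg: ICPConfig = ICPConfig(),
    roles=None,
) -> ICPResult:
    """Register ``source`` (reference) onto ``target`` (current frame).

    Alternates nearest-neighbour correspondence with a Kabsch update until
    the RMS change falls below ``cfg.tolerance_mm``. ``correspondence=
    'labeled'`` pairs markers by label instead (the exact oracle path for
    well-separated markers). Only markers valid in *both* clouds, within the
    requested ``roles``, participate.
    """
    sel_src = source.valid & (source.role_mask(roles) if roles is not None else True)
    sel_tgt = target.valid & (target.role_mask(roles) if roles is not None else True)
    # only markers valid in BOTH clouds participate: a marker dropped in one
    # frame is excluded from the fit entirely, never mis-corresponded
    tgt_valid = dict(zip(target.labels, sel_tgt))
    src_valid = dict(zip(source.labels, sel_src))
    sel_src = sel_src & np.array([tgt_valid.get(lab, False) for lab in source.labels])
    sel_tgt = sel_tgt & np.array([src_valid.get(lab, False) for lab in target.labels])

    if cfg.correspondence == "labeled":
        common = [
            i for i, lab in enumerate(source.labels)
            if sel_src[i] and lab in target.labels and sel_tgt[target.index(lab)]
        ]
        if len(common) < 3:
            raise RegistrationError(f"only {len(common)} usable markers (< 3)")
        src = source.points[common]
        tgt = np.array([target.get(source.labels[i]) for i in common])
        transform = kabsch(src, tgt)
        rms = _rms(transform.apply(src), tgt)
        return ICPResult(transform, rms, 1, True, (rms,), len(common))

    src = source.points[sel_src]
    tgt = target.points[sel_tgt]
    if src.shape[0] < 3 or tgt.shape[0] < 3:
        raise RegistrationError(
            f"only {min(src.shape[0], tgt.shape[0])} usable markers (< 3)"
        )
    tree = cKDTree(tgt)
    transform = cfg.init
    history: list[float] = []
    prev_rms = np.inf
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        moved = transform.apply(src)
        _, nn = tree.query(moved)
        transform = kabsch(src, tgt[nn])
        rms = _rms(transform.apply(src), tgt[nn])
        history.append(rms)
        if rms < cfg.tolerance_mm or prev_rms - rms < cfg.tolerance_mm:
            converged = True
            break
        prev_rms = rms
    if not converged:
        warnings.warn(
            f"ICP did not converge in {cfg.max_iterations} iterations "
            f"(last RMS {history[-1]:.4g} mm)",
            RuntimeWarning,
        )
    return ICPResult(transform, history[-1], it, converged, tuple(history), src.shape[0])


def smooth_series(
    series: np.ndarray,
    window: int = 5,
    mode: str = "centered",
) -> np.ndarray:
    """Per-axis moving average over time of a (T, ...) position series.

    ``mode='centered'`` (default) averages the window centred on each frame
    with edges truncated to the available frames; ``mode='trailing'`` uses
    the window ending at each frame. NaNs (invalid marker-frames) are
    ignored within the window. Applied to respiratory-surrogate markers
    only, whose breathing motion the 5-s sampling cannot resolve.
    """
    arr = np.asarray(series, float)
    if arr.shape[0] < 1:
        raise ValueError("series must contain at least one frame")
    if window < 1:
        raise ValueError("window must be >= 1")
    flat = arr.reshape(arr.shape[0], -1)
    df = pd.DataFrame(flat)
    if mode == "centered":
        sm = df.rolling(window, center=True, min_periods=1).mean()
    elif mode == "trailing":
        sm = df.rolling(window, center=False, min_periods=1).mean()
    else:
        raise ValueError("mode must be 'centered' or 'trailing'")
    return sm.to_numpy().reshape(arr.shape)


def set_origin(
    reference: LabeledCloud,
    setup_type: str,
    axis_lr: float = DEFAULT_AXIS_LR,
    axis_ap: float = DEFAULT_AXIS_AP,
) -> np.ndarray:
    """Reporting origin of the transformation matrices.

    The origin sits on the chair's vertical rotation axis at the SI height
    of the anchor marker (A2 for abdominal setups, H1 for head-and-neck) in
    the reference image.
    """
    try:
        anchor = ANCHOR_MARKER[setup_type]
    except KeyError:
        raise ValueError(f"setup_type must be one of {sorted(ANCHOR_MARKER)}") from None
    idx = reference.index(anchor)
    if not reference.valid[idx]:
        raise RegistrationError(f"anchor marker {anchor} invalid in reference image")
    return np.array([axis_lr, axis_ap, reference.points[idx, 2]], float)


@dataclass(frozen=True)
class TrackConfig:
    setup_type: str = "abdominal"
    icp: ICPConfig = field(default_factory=ICPConfig)
    smooth_window: int = 5
    smooth_mode: str = "centered"
    smooth: bool = True   # intra-fractional sessions only; single inter-fraction
    #                       images are never smoothed


@dataclass
class TrackResult:
    """Per-frame body and mask transforms plus per-thigh-marker displacement."""

    times: np.ndarray
    body: list                 # RigidTransform | None per frame
    mask: list
    body_rms_mm: np.ndarray
    mask_rms_mm: np.ndarray
    body_n_used: np.ndarray
    mask_n_used: np.ndarray
    thigh_displacement: dict   # label -> (T, 3) array, NaN when invalid
    unregistered: np.ndarray   # (T,) bool: either body or mask fit failed


def _register_role(
    reference: LabeledCloud,
    frame: LabeledCloud,
    roles,
    cfg: TrackConfig,
):
    try:
        res = icp(reference, frame, cfg.icp, roles=roles)
        return res.transform, res.rms_mm, res.n_points
    except RegistrationError:
        return None, np.nan, 0


def track_sequence(frames: list[LabeledCloud], cfg: TrackConfig = TrackConfig()) -> TrackResult:
    """Track body and mask transforms across a session.

    ``frames[0]`` is the reference image. Respiratory markers are smoothed
    over ``cfg.smooth_window`` frames before the body registration (when
    ``cfg.smooth``); thigh markers are excluded from the body fit and
    reported as raw per-marker displacements. Frames with fewer than three
    usable markers for a fit are flagged unregistered and the pipeline
    continues.
    """
    if not frames:
        raise ValueError("no frames to track")
    reference = frames[0]
    n = len(reference.labels)
    t_count = len(frames)
    times = np.array([f.time_s for f in frames], float)

    # stack positions over time, NaN where invalid, for the smoothing pass
    pos = np.full((t_count, n, 3), np.nan)
    val = np.zeros((t_count, n), bool)
    for t, f in enumerate(frames):
        if f.labels != reference.labels:
            raise ValueError("all frames must share the reference label set")
        pos[t][f.valid] = f.points[f.valid]
        val[t] = f.valid

    resp = reference.role_mask("body_respiratory")
    if cfg.smooth and cfg.smooth_window > 1 and resp.any():
        sm = smooth_series(pos[:, resp, :], cfg.smooth_window, cfg.smooth_mode)
        pos = pos.copy()
        pos[:, resp, :] = sm
        # a smoothed sample is usable whenever any frame in its window was
        val[:, resp] = np.isfinite(sm).all(axis=2)

    work = [
        frames[t].with_points(np.nan_to_num(pos[t]), valid=val[t])
        for t in range(t_count)
    ]
    ref_work = work[0]

    body_t, mask_t = [], []
    body_rms = np.full(t_count, np.nan)
    mask_rms = np.full(t_count, np.nan)
    body_n = np.zeros(t_count, int)
    mask_n = np.zeros(t_count, int)
    unreg = np.zeros(t_count, bool)
    for t in range(t_count):
        tb, rb, nb = _register_role(ref_work, work[t], BODY_ROLES, cfg)
        tm, rm, nm = _register_role(ref_work, work[t], "mask", cfg)
        body_t.append(tb)
        mask_t.append(tm)
        body_rms[t], mask_rms[t] = rb, rm
        body_n[t], mask_n[t] = nb, nm
        unreg[t] = tb is None or tm is None

    thigh = {}
    for i, lab in enumerate(reference.labels):
        if reference.roles[i] != "thigh":
            continue
        disp = np.full((t_count, 3), np.nan)
        if reference.valid[i]:
            ok = val[:, i]
            disp[ok] = pos[ok, i, :] - reference.points[i]
        thigh[lab] = disp

    return TrackResult(
        times=times,
        body=body_t,
        mask=mask_t,
        body_rms_mm=body_rms,
        mask_rms_mm=mask_rms,
        body_n_used=body_n,
        mask_n_used=mask_n,
        thigh_displacement=thigh,
        unregistered=unreg,
    )
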