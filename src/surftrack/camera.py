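"""Pinhole camera model, extrinsic calibration, triangulation, grid verification.

The imaging chain reconstructs 3D marker positions from three fixed
high-resolution cameras (front, left, right). Intrinsics are inputs
(pre-calibrated); this module covers:

* projection through a pinhole model with Brown-Conrady distortion,
* extrinsic calibration of each camera by nonlinear minimisation of the
  reprojection error against known grid-plate points,
* pairwise triangulation (DLT followed by reprojection-error refinement),
* the camera-pair selection rule (front+left for left-side markers,
  front+right for right-side, lateral pair as fallback),
* accuracy verification on a held-out grid-plate pose, reported per camera
  pair as per-axis and 3D error statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform

__all__ = [
    "CameraIntrinsics",
    "CameraPose",
    "Camera",
    "GridPlate",
    "GridAccuracyReport",
    "CalibrationError",
    "DegenerateGeometryError",
    "project",
    "undistort_pixels",
    "calibrate_extrinsics",
    "triangulate_pair",
    "triangulate_points",
    "select_camera_pair",
    "verify_grid",
    "CAMERA_PAIRS",
]

CAMERA_NAMES = ("front", "left", "right")
CAMERA_PAIRS = (("front", "left"), ("front", "right"), ("left", "right"))


class CalibrationError(RuntimeError):
    pass


class DegenerateGeometryError(ValueError):
    """Raised when camera/ray geometry is too ill-conditioned to triangulate."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels plus Brown-Conrady distortion coefficients."""

    fx: float
    fy: float
    cx: float
    cy: float
    skew: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    width: int = 5496
    height: int = 3672

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside image bounds")

    @classmethod
    def from_lens(
        cls,
        focal_mm: float = 25.0,
        pixel_pitch_mm: float = 0.0024,
        width: int = 5496,
        height: int = 3672,
    ) -> "CameraIntrinsics":
        """Ideal intrinsics from lens focal length and sensor pixel pitch."""
        f_px = focal_mm / pixel_pitch_mm
        return cls(fx=f_px, fy=f_px, cx=width / 2.0, cy=height / 2.0,
                   width=width, height=height)

    def distortion(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.p1, self.p2], float)

    def in_bounds(self, px: np.ndarray) -> np.ndarray:
        px = np.atleast_2d(np.asarray(px, float))
        return (
            (px[:, 0] >= 0) & (px[:, 0] <= self.width - 1)
            & (px[:, 1] >= 0) & (px[:, 1] <= self.height - 1)
        )


@dataclass(frozen=True)
class CameraPose:
    """World-to-camera rigid transform plus camera identifier."""

    transform: RigidTransform
    name: str = "camera"

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.transform.rotation.T @ self.transform.translation


@dataclass(frozen=True)
class Camera:
    name: str
    intrinsics: CameraIntrinsics
    pose: CameraPose


# ---------------------------------------------------------------------------
# projection


def _distort_normalized(xy: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + intr.k1 * r2 + intr.k2 * r2**2 + intr.k3 * r2**3
    xd = x * radial + 2 * intr.p1 * x * y + intr.p2 * (r2 + 2 * x * x)
    yd = y * radial + intr.p1 * (r2 + 2 * y * y) + 2 * intr.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def project(intr: CameraIntrinsics, pose: CameraPose, points: np.ndarray) -> np.ndarray:
    """Project world point(s) (..., 3) in mm to pixel coordinates (..., 2).

    Raises :class:`ValueError` for points at or behind the camera plane.
    """
    p = np.asarray(points, float)
    single = p.ndim == 1
    pc = pose.transform.apply(p.reshape(-1, 3))
    z = pc[:, 2]
    if np.any(z <= 1e-9):
        raise ValueError("point at or behind the camera plane")
    xy = pc[:, :2] / z[:, None]
    xd = _distort_normalized(xy, intr)
    u = intr.fx * xd[:, 0] + intr.skew * xd[:, 1] + intr.cx
    v = intr.fy * xd[:, 1] + intr.cy
    px = np.stack([u, v], axis=-1)
    return px[0] if single else px.reshape(p.shape[:-1] + (2,))


def undistort_pixels(intr: CameraIntrinsics, px: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Map pixel coordinates to ideal *normalized* image coordinates.

    Inverts the distortion polynomial by fixed-point iteration (exact to
    machine precision for the mild coefficients of machine-vision lenses).
    """
    px = np.asarray(px, float)
    single = px.ndim == 1
    p = np.atleast_2d(px)
    yd = (p[:, 1] - intr.cy) / intr.fy
    xd = (p[:, 0] - intr.cx - intr.skew * yd) / intr.fx
    d = np.stack([xd, yd], axis=-1)
    xy = d.copy()
    for _ in range(n_iter):
        delta = _distort_normalized(xy, intr) - xy
        xy = d - delta
    return xy[0] if single else xy.reshape(px.shape)


# ---------------------------------------------------------------------------
# extrinsic calibration


def _pose_from_params(params: np.ndarray, name: str) -> CameraPose:
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    return CameraPose(RigidTransform(rot, params[3:]), name=name)


def _params_from_pose(pose: CameraPose) -> np.ndarray:
    rv = Rotation.from_matrix(pose.transform.rotation).as_rotvec()
    return np.concatenate([rv, pose.transform.translation])


def calibrate_extrinsics(
    intr: CameraIntrinsics,
    object_points: np.ndarray,
    image_points: np.ndarray,
    init: CameraPose,
) -> tuple[CameraPose, float]:
    """Fit the world-to-camera pose minimising squared pixel reprojection error.

    Parameters
    ----------
    object_points
        (N, 3) known 3D positions (mm) of detected grid points.
    image_points
        (N, 2) detected pixel positions.
    init
        Initial pose estimate (identity-of-rig-design level accuracy suffices;
        the optimum is insensitive to moderate init perturbations).

    Returns
    -------
    (pose, rms_px)
        The optimal pose and the RMS reprojection error (pixels, per point).
    """
    obj = np.asarray(object_points, float).reshape(-1, 3)
    img = np.asarray(image_points, float).reshape(-1, 2)
    if obj.shape[0] != img.shape[0]:
        raise ValueError("object/image point counts differ")
    if obj.shape[0] < 6:
        raise CalibrationError(f"need >= 6 observations, got {obj.shape[0]}")
    centered = obj - obj.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
        raise CalibrationError("observations are collinear: pose not identifiable")

    def residuals(params: np.ndarray) -> np.ndarray:
        pose = _pose_from_params(params, init.name)
        return (project(intr, pose, obj) - img).ravel()

    res = least_squares(
        residuals,
        _params_from_pose(init),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not res.success:
        raise CalibrationError(f"pose optimisation failed: {res.message}")
    pose = _pose_from_params(res.x, init.name)
    # per-coordinate RMS, so the optimum on noisy data sits at the noise floor
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return pose, rms


# ---------------------------------------------------------------------------
# triangulation


def _ray(intr: CameraIntrinsics, pose: CameraPose, px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World-frame (origin, unit direction) of the back-projected pixel ray."""
    xy = undistort_pixels(intr, px)
    d_cam = np.array([xy[0], xy[1], 1.0])
    rot_t = pose.transform.rotation.T
    direction = rot_t @ d_cam
    return pose.center, direction / np.linalg.norm(direction)


def triangulate_pair(
    cam_a: tuple[CameraIntrinsics, CameraPose],
    cam_b: tuple[CameraIntrinsics, CameraPose],
    px_a: np.ndarray,
    px_b: np.ndarray,
    min_angle_deg: float = 1.0,
    refine: bool = True,
) -> tuple[np.ndarray, float]:
    """Triangulate one 3D point (mm) from a calibrated camera pair.

    A linear DLT estimate in normalized coordinates is refined by
    Gauss-Newton on the summed squared pixel reprojection error. Returns the
    point and the RMS reprojection residual in pixels.

    Raises :class:`DegenerateGeometryError` when the back-projected rays
    subtend less than ``min_angle_deg``.
    """
    intr_a, pose_a = cam_a
    intr_b, pose_b = cam_b
    oa, da = _ray(intr_a, pose_a, np.asarray(px_a, float))
    ob, db = _ray(intr_b, pose_b, np.asarray(px_b, float))
    cos_angle = abs(float(np.dot(da, db)))
    if cos_angle > np.cos(np.deg2rad(min_angle_deg)):
        raise DegenerateGeometryError(
            f"rays subtend {np.rad2deg(np.arccos(min(cos_angle, 1.0))):.3f} deg "
            f"< {min_angle_deg} deg: triangulation ill-conditioned"
        )

    # DLT rows: (r1 - x r3) X = x t3 - t1 etc., in normalized coordinates
    rows, rhs = [], []
    for (intr, pose, px) in ((intr_a, pose_a, px_a), (intr_b, pose_b, px_b)):
        x, y = undistort_pixels(intr, np.asarray(px, float))
        rot, tr = pose.transform.rotation, pose.transform.translation
        rows.append(rot[0] - x * rot[2]); rhs.append(x * tr[2] - tr[0])
        rows.append(rot[1] - y * rot[2]); rhs.append(y * tr[2] - tr[1])
    point, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)

    cams = ((intr_a, pose_a, np.asarray(px_a, float)), (intr_b, pose_b, np.asarray(px_b, float)))

    def resid(p: np.ndarray) -> np.ndarray:
        return np.concatenate([project(i, q, p) - px for (i, q, px) in cams])

    if refine:
        # Gauss-Newton, forward-difference Jacobian over the 3 coordinates
        p = point.copy()
        for _ in range(10):
            r0 = resid(p)
            jac = np.empty((4, 3))
            eps = 1e-4
            for j in range(3):
                dp = np.zeros(3)
                dp[j] = eps
                jac[:, j] = (resid(p + dp) - r0) / eps
            try:
                step = np.linalg.lstsq(jac, -r0, rcond=None)[0]
            except np.linalg.LinAlgError:  # pragma: no cover
                break
            p = p + step
            if np.linalg.norm(step) < 1e-12:
                break
        point = p

    r = resid(point)
    rms = float(np.sqrt(np.mean(r**2)))
    return point, rms


def triangulate_points(
    cam_a,
    cam_b,
    px_a,
    px_b,
    min_angle_deg: float = 1.0,
    refine: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched triangulation of N pixel pairs (same semantics as
    :func:`triangulate_pair`, vectorised over points)."""
    intr_a, pose_a = cam_a
    intr_b, pose_b = cam_b
    px_a = np.atleast_2d(np.asarray(px_a, float))
    px_b = np.atleast_2d(np.asarray(px_b, float))
    n = px_a.shape[0]
    xa = np.atleast_2d(undistort_pixels(intr_a, px_a))
    xb = np.atleast_2d(undistort_pixels(intr_b, px_b))

    # conditioning: angle between back-projected rays
    def _dirs(pose, xy):
        d = np.column_stack([xy, np.ones(len(xy))]) @ pose.transform.rotation
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    cosang = np.abs(np.sum(_dirs(pose_a, xa) * _dirs(pose_b, xb), axis=1))
    if np.any(cosang > np.cos(np.deg2rad(min_angle_deg))):
        worst = np.rad2deg(np.arccos(np.clip(cosang.min(), -1, 1)))
        raise DegenerateGeometryError(
            f"rays subtend as little as {worst:.3f} deg < {min_angle_deg} deg"
        )

    # batched DLT via normal equations
    amat = np.empty((n, 4, 3))
    bvec = np.empty((n, 4))
    for k, (pose, xy) in enumerate(((pose_a, xa), (pose_b, xb))):
        rot, tr = pose.transform.rotation, pose.transform.translation
        amat[:, 2 * k] = rot[0] - xy[:, :1] * rot[2]
        amat[:, 2 * k + 1] = rot[1] - xy[:, 1:2] * rot[2]
        bvec[:, 2 * k] = xy[:, 0] * tr[2] - tr[0]
        bvec[:, 2 * k + 1] = xy[:, 1] * tr[2] - tr[1]
    ata = np.einsum("nij,nik->njk", amat, amat)
    atb = np.einsum("nij,ni->nj", amat, bvec)
    pts = np.linalg.solve(ata, atb[..., None])[..., 0]

    def resid(p: np.ndarray) -> np.ndarray:
        ra = project(intr_a, pose_a, p) - px_a
        rb = project(intr_b, pose_b, p) - px_b
        return np.concatenate([ra, rb], axis=1)  # (n, 4)

    if refine:
        for _ in range(3):  # Gauss-Newton; the DLT start is near-optimal
            r0 = resid(pts)
            jac = np.empty((n, 4, 3))
            eps = 1e-4
            for j in range(3):
                dp = np.zeros(3)
                dp[j] = eps
                jac[:, :, j] = (resid(pts + dp) - r0) / eps
            jtj = np.einsum("nij,nik->njk", jac, jac)
            jtr = np.einsum("nij,ni->nj", jac, r0)
            step = -np.linalg.solve(jtj, jtr[..., None])[..., 0]
            pts = pts + step
            if np.abs(step).max() < 1e-10:
                break

    rms = np.sqrt(np.mean(resid(pts) ** 2, axis=1))
    return pts, rms


def select_camera_pair(
    marker_side: str,
    availability: dict[str, bool],
) -> tuple[str, str] | None:
    """Camera pair used to triangulate a marker.

    Left-side markers use (front, left) and right-side markers
    (front, right); the lateral (left, right) pair is the fallback when the
    front camera cannot see the marker. Central markers default to
    (front, left). Returns ``None`` when fewer than two cameras see the
    marker (the marker is then flagged invalid, never dropped silently).
    """
    if marker_side not in ("left", "right", "central"):
        raise ValueError(f"unknown marker side {marker_side!r}")
    ok = {c: bool(availability.get(c, False)) for c in CAMERA_NAMES}
    if sum(ok.values()) < 2:
        return None
    lateral = "right" if marker_side == "right" else "left"
    if ok["front"] and ok[lateral]:
        return ("front", lateral)
    other = "left" if lateral == "right" else "right"
    if ok["front"] and ok[other]:
        return ("front", other)
    return ("left", "right")


# ---------------------------------------------------------------------------
# grid plate and verification


@dataclass(frozen=True)
class GridPlate:
    """Planar calibration plate: ``rows x cols`` points at uniform spacing."""

    pose: RigidTransform
    rows: int = 41
    cols: int = 58
    spacing_mm: float = 5.0

    @property
    def n_points(self) -> int:
        return self.rows * self.cols

    def local_points(self) -> np.ndarray:
        """Grid points in the plate frame, centred on the plate, z = 0."""
        r = np.arange(self.rows) - (self.rows - 1) / 2.0
        c = np.arange(self.cols) - (self.cols - 1) / 2.0
        cc, rr = np.meshgrid(c, r)
        pts = np.stack(
            [cc.ravel() * self.spacing_mm, np.zeros(self.n_points), -rr.ravel() * self.spacing_mm],
            axis=1,
        )
        return pts

    def world_points(self) -> np.ndarray:
        return self.pose.apply(self.local_points())

    def point_index(self) -> pd.DataFrame:
        rr, cc = np.divmod(np.arange(self.n_points), self.cols)
        return pd.DataFrame({"row": rr, "col": cc})


@dataclass(frozen=True)
class GridAccuracyReport:
    """Per-camera-pair accuracy of the triangulated grid against ground truth.

    ``per_pair[pair][axis]`` holds (mean, sd, p95) of absolute errors in mm
    for axis in ("lr", "ap", "si", "3d"); the 3D error of each point is the
    Euclidean norm of its per-axis errors. 95th percentiles use linear
    interpolation between order statistics.
    """

    per_pair: dict
    n_points: dict
    n_excluded: dict
    percentile_rule: str = "linear"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, axes in self.per_pair.items():
            for axis, (mean, sd, p95) in axes.items():
                rows.append({
                    "pair": "-".join(pair), "axis": axis,
                    "mean_mm": mean, "sd_mm": sd, "p95_mm": p95,
                    "n": self.n_points[pair],
                })
        return pd.DataFrame(rows)


def _error_stats(abs_err: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.mean(abs_err)),
        float(np.std(abs_err, ddof=1)) if abs_err.size > 1 else 0.0,
        float(np.percentile(abs_err, 95, method="linear")),
    )


def verify_grid(
    cameras: dict[str, Camera],
    plate: GridPlate,
    detections: pd.DataFrame,
) -> GridAccuracyReport:
    """Triangulate a held-out grid-plate pose and report errors per camera pair.

    ``detections`` columns: camera, row, col, u_px, v_px, valid. Points
    missing or invalid in either camera of a pair are excluded (counted).
    """
    truth = plate.point_index()
    truth[["x", "y", "z"]] = plate.world_points()
    per_pair, n_points, n_excluded = {}, {}, {}
    det = detections[detections["valid"].astype(bool)]
    for pair in CAMERA_PAIRS:
        a, b = pair
        da = det[det["camera"] == a][["row", "col", "u_px", "v_px"]]
        db = det[det["camera"] == b][["row", "col", "u_px", "v_px"]]
        merged = da.merge(db, on=["row", "col"], suffixes=("_a", "_b"))
        merged = merged.merge(truth, on=["row", "col"])
        n_excluded[pair] = int(plate.n_points - len(merged))
        if len(merged) == 0:
            per_pair[pair] = {}
            n_points[pair] = 0
            continue
        pts, _ = triangulate_points(
            (cameras[a].intrinsics, cameras[a].pose),
            (cameras[b].intrinsics, cameras[b].pose),
            merged[["u_px_a", "v_px_a"]].to_numpy(),
            merged[["u_px_b", "v_px_b"]].to_numpy(),
        )
        err = pts - merged[["x", "y", "z"]].to_numpy()
        abs_err = np.abs(err)
        e3d = np.linalg.norm(err, axis=1)
        per_pair[pair] = {
            "lr": _error_stats(abs_err[:, 0]),
            "ap": _error_stats(abs_err[:, 1]),
            "si": _error_stats(abs_err[:, 2]),
            "3d": _error_stats(e3d),
        }
        n_points[pair] = int(len(merged))
    return GridAccuracyReport(per_pair=per_pair, n_points=n_points, n_excluded=n_excluded)
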