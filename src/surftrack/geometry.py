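"""Rigid-body transform algebra and 6-DoF displacement decomposition.

Coordinate convention (the "world frame" of an analysis run):

* ``x`` = LR, positive toward the patient's **left**
* ``y`` = AP, positive toward **anterior**
* ``z`` = SI, positive toward **superior**

All lengths are millimetres, all angles degrees. The basis is right-handed
and fixed for an entire run. Rotational displacements are reported as
*pitch* (rotation about the LR axis), *roll* (about the AP axis) and *yaw*
(about the SI axis), with the right-hand rule about each positive axis.

A :class:`RigidTransform` maps coordinates of the *reference* frame into the
*current* frame: ``p_current = R @ p_reference + t``. The displacement a
transform represents is therefore "how far did the object move relative to
where it was in the reference image".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AXIS_NAMES",
    "RigidTransform",
    "Displacement6D",
    "GimbalLockWarning",
    "compose",
    "invert",
    "relative_transform",
    "to_displacement",
    "from_displacement",
]

#: component order used throughout the package
AXIS_NAMES = ("lr", "ap", "si", "pitch", "roll", "yaw")

# Intrinsic Euler sequence used to decompose rotations: yaw about SI (z),
# then pitch about LR (x), then roll about AP (y). All observed clinical
# rotations are ~1 degree or less, where the sequence choice is numerically
# immaterial (tested); it is configurable for completeness.
DEFAULT_EULER_SEQ = "ZXY"

_ORTHO_TOL = 1e-8


class GimbalLockWarning(UserWarning):
    """Pitch within a degree of +/-90 deg; Euler decomposition ill-conditioned."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform ``p -> rotation @ p + translation``.

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1;
    ``translation`` is in millimetres.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        if rot.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {rot.shape}")
        if not np.all(np.isfinite(rot)) or not np.all(np.isfinite(tr)):
            raise ValueError("non-finite entries in rigid transform")
        err = np.abs(rot.T @ rot - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ValueError(f"rotation not orthonormal (max |R^T R - I| = {err:.3e})")
        if abs(np.linalg.det(rot) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation must be proper (det = +1); reflections rejected")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    # ---- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Axis-angle constructor; ``rotvec_deg`` is a rotation vector in degrees."""
        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation, float))

    # ---- algebra ------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or a stack of points (..., 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        return compose(self, inner)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    # ---- serialization ------------------------------------------------
    def to_dict(self, origin=None) -> dict:
        d = {
            "rotation_row_major": [float(v) for v in self.rotation.ravel()],
            "translation_mm": [float(v) for v in self.translation],
        }
        if origin is not None:
            d["origin_mm"] = [float(v) for v in np.asarray(origin, float)]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        rot = np.asarray(d["rotation_row_major"], float).reshape(3, 3)
        return cls(rot, np.asarray(d["translation_mm"], float))


@dataclass(frozen=True)
class Displacement6D:
    """Six-component displacement: translations in mm, rotations in degrees.

    ``pitch`` rotates about LR, ``roll`` about AP, ``yaw`` about SI.
    """

    lr: float
    ap: float
    si: float
    pitch: float
    roll: float
    yaw: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("displacement components must be finite")
        for name in ("pitch", "roll", "yaw"):
            a = getattr(self, name)
            if not (-180.0 < a <= 180.0):
                raise ValueError(f"{name} = {a} outside (-180, 180] degrees")

    def as_array(self) -> np.ndarray:
        return np.array([self.lr, self.ap, self.si, self.pitch, self.roll, self.yaw], float)

    @classmethod
    def from_array(cls, arr) -> "Displacement6D":
        arr = np.asarray(arr, float).reshape(6)
        return cls(*[float(v) for v in arr])

    @classmethod
    def zero(cls) -> "Displacement6D":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def translation(self) -> np.ndarray:
        return np.array([self.lr, self.ap, self.si], float)


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Transform equal to applying ``inner`` first, then ``outer``."""
    return RigidTransform(
        outer.rotation @ inner.rotation,
        outer.rotation @ inner.translation + outer.translation,
    )


def invert(t: RigidTransform) -> RigidTransform:
    rt = t.rotation.T
    return RigidTransform(rt, -rt @ t.translation)


def relative_transform(m_body: RigidTransform, m_mask: RigidTransform) -> RigidTransform:
    """Relative rigid motion of the body with respect to the mask.

    ``M_rel = M_body @ M_mask^-1``: identity whenever the body moves
    exactly with the mask.
    """
    return compose(m_body, invert(m_mask))


def _seq_angle_order(seq: str) -> tuple[int, int, int]:
    """Indices of (pitch, roll, yaw) within the Euler-angle tuple of ``seq``."""
    seq = seq.upper()
    if sorted(seq) != ["X", "Y", "Z"]:
        raise ValueError(f"Euler sequence must be a permutation of XYZ, got {seq!r}")
    return seq.index("X"), seq.index("Y"), seq.index("Z")


def to_displacement(
    t: RigidTransform,
    origin,
    seq: str = DEFAULT_EULER_SEQ,
) -> Displacement6D:
    """Decompose a rigid transform into a 6-DoF displacement about ``origin``.

    The translational part is the motion of the reporting origin itself,
    ``t(origin) - origin``; the rotational part is the intrinsic Euler
    decomposition of the rotation in sequence ``seq`` (default yaw-pitch-roll
    about SI, LR, AP). Warns on gimbal-lock proximity, which never occurs for
    clinical-scale motions.
    """
    origin = np.asarray(origin, float).reshape(3)
    trans = t.apply(origin) - origin
    ix, iy, iz = _seq_angle_order(seq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy gimbal warning replaced by ours
        angles = Rotation.from_matrix(t.rotation).as_euler(seq.upper(), degrees=True)
    pitch, roll, yaw = angles[ix], angles[iy], angles[iz]
    # middle angle of the sequence is the gimbal-locked one
    middle = angles[1]
    if abs(abs(middle) - 90.0) < 1.0:
        warnings.warn(
            f"Euler middle angle {middle:.2f} deg near +/-90: decomposition ill-conditioned",
            GimbalLockWarning,
        )
    return Displacement6D(
        float(trans[0]), float(trans[1]), float(trans[2]),
        float(pitch), float(roll), float(yaw),
    )


def from_displacement(
    d: Displacement6D,
    origin,
    seq: str = DEFAULT_EULER_SEQ,
) -> RigidTransform:
    """Inverse of :func:`to_displacement` about the same origin."""
    origin = np.asarray(origin, float).reshape(3)
    ix, iy, iz = _seq_angle_order(seq)
    angles = np.empty(3)
    angles[ix], angles[iy], angles[iz] = d.pitch, d.roll, d.yaw
    rot = Rotation.from_euler(seq.upper(), angles, degrees=True).as_matrix()
    # t(origin) - origin = trans  =>  t = trans + origin - R @ origin
    translation = d.translation() + origin - rot @ origin
    return RigidTransform(rot, translation)
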