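"""Sub-pixel detection of dark circular markers inside per-marker image patches.

Each surface marker is a 5-mm black disc. Detection follows the classic
patch pipeline: a static patch box per marker, binarisation (Otsu by default,
fixed threshold optionally), and the centroid of the dark pixels as the
sub-pixel 2D marker position.

Pixel coordinate convention: 0-based, pixel ``(row i, col j)`` has centre
``(u, v) = (j, i)``; ``u`` increases with image column, ``v`` with row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "ImagePatch",
    "Detection2D",
    "binarize",
    "centroid_of_dark",
    "detect_frame",
    "DEFAULT_MIN_AREA",
]

#: minimum dark-pixel count for a valid detection (rejects speckle)
DEFAULT_MIN_AREA = 10


@dataclass(frozen=True)
class ImagePatch:
    """8-bit grayscale patch cut from a full camera image."""

    pixels: np.ndarray
    offset: tuple[float, float]  # (u0, v0) of patch pixel (0, 0) in the full image
    label: str = ""
    camera: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("patch must be a non-empty 2D array")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class Detection2D:
    """Sub-pixel marker detection in one camera image."""

    label: str
    camera: str
    u_px: float
    v_px: float
    valid: bool
    dark_px: int


def binarize(patch: ImagePatch, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Binarise a patch: dark (marker) pixels -> 0, background -> 1.

    ``method='otsu'`` picks the threshold maximising between-class variance;
    ``method='fixed'`` uses ``threshold``. Pixels at or below the threshold
    are marked dark. A uniform patch yields zero dark pixels (the detection
    is then flagged invalid downstream).
    """
    px = patch.pixels
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarisation requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if px.min() == px.max():
            return np.ones_like(px, dtype=np.uint8)
        thr = float(threshold_otsu(px))
    else:
        raise ValueError(f"unknown binarisation method {method!r}")
    return np.where(px <= thr, 0, 1).astype(np.uint8)


def centroid_of_dark(
    binary: np.ndarray,
    offset: tuple[float, float] = (0.0, 0.0),
    label: str = "",
    camera: str = "",
    min_area: int = DEFAULT_MIN_AREA,
) -> Detection2D:
    """Centroid of zero-valued pixels in a binarised patch (pixel centres).

    Detections with fewer than ``min_area`` dark pixels are flagged invalid
    (mirrors markers that were removed or covered during a session).
    """
    rows, cols = np.nonzero(np.asarray(binary) == 0)
    n_dark = int(rows.size)
    if n_dark < min_area:
        return Detection2D(label, camera, np.nan, np.nan, False, n_dark)
    u = float(cols.mean() + offset[0])
    v = float(rows.mean() + offset[1])
    return Detection2D(label, camera, u, v, True, n_dark)


def cut_patch(image: np.ndarray, box: tuple[int, int, int, int], label: str = "", camera: str = "") -> ImagePatch:
    """Extract the patch at box (u0, v0, width, height); box must lie inside the image."""
    u0, v0, w, h = (int(b) for b in box)
    hgt, wid = image.shape[:2]
    if u0 < 0 or v0 < 0 or u0 + w > wid or v0 + h > hgt or w <= 0 or h <= 0:
        raise ValueError(f"patch box {box} outside image of shape {(hgt, wid)}")
    return ImagePatch(image[v0:v0 + h, u0:u0 + w], (float(u0), float(v0)), label, camera)


def detect_frame(
    image: np.ndarray,
    boxes: dict[str, tuple[int, int, int, int]],
    camera: str = "",
    method: str = "otsu",
    threshold: float | None = None,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[Detection2D]:
    """Detect every configured marker in a full frame.

    Returns exactly one :class:`Detection2D` per configured marker; markers
    whose patch contains no resolvable dark blob are flagged invalid, never
    dropped.
    """
    out = []
    for label, box in boxes.items():
        patch = cut_patch(image, box, label=label, camera=camera)
        binary = binarize(patch, method=method, threshold=threshold)
        out.append(
            centroid_of_dark(binary, patch.offset, label=label, camera=camera, min_area=min_area)
        )
    return out
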