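"""Eye-landmark face alignment and chip extraction.

A face chip is the canonical input of the recognition network: a square
grayscale image in which the eyes sit at fixed positions.  Given the
two eye centers in a source photograph, the face is rotated in-plane so
the inter-ocular axis becomes horizontal, scaled so each eye lies
0.5 x IPD from its nearest side edge and 0.6 x IPD below the top edge
(IPD = inter-pupil distance, the Euclidean distance between the eye
centers), and resampled to 112 x 112 pixels.

With side margins of 0.5 x IPD the chip width is 2 x IPD, so in chip
coordinates the inter-pupil distance is always 112 / 2 = 56 px and the
eyes land at (28, 33.6) and (84, 33.6) regardless of the source pose.

Coordinates are 0-based pixel indices, x to the right, y down; a pixel
center is at integral coordinates.  "Left eye" means the eye with the
smaller x in the source image (the viewer's left).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "EyePair",
    "AlignmentTransform",
    "ChipGeometry",
    "interpupil_distance",
    "rotation_matrix",
    "chip_transform",
    "transform_points",
    "align_and_chip",
    "to_grayscale",
]


@dataclass(frozen=True)
class EyePair:
    """Eye centers in source-image pixel coordinates."""

    left: tuple[float, float]
    right: tuple[float, float]

    def __post_init__(self):
        if tuple(self.left) == tuple(self.right):
            raise ValueError("eye centers must be distinct points")


@dataclass(frozen=True)
class ChipGeometry:
    """Margins (in units of IPD) and the square chip size in pixels."""

    side_margin_ratio: float = 0.5
    top_margin_ratio: float = 0.6
    chip_size: int = 112

    @property
    def chip_ipd(self) -> float:
        """Inter-pupil distance in chip coordinates.

        chip width = IPD' * (1 + 2 * side_margin) => IPD' = size / 2
        for the default 0.5 margin.
        """
        return self.chip_size / (1.0 + 2.0 * self.side_margin_ratio)

    @property
    def chip_eyes(self) -> tuple[tuple[float, float], tuple[float, float]]:
        ipd = self.chip_ipd
        y = self.top_margin_ratio * ipd
        x0 = self.side_margin_ratio * ipd
        return (x0, y), (x0 + ipd, y)


@dataclass(frozen=True)
class AlignmentTransform:
    """In-plane rotation by theta about the eye midpoint.

    ``matrix`` is the 2x3 affine [[cos t, -sin t, x(1-cos t)+y sin t],
    [sin t, cos t, y(1-cos t)-x sin t]] for midpoint (x, y): it maps a
    point p to R(theta) (p - mid) + mid.
    """

    theta: float
    midpoint: tuple[float, float]
    matrix: np.ndarray = field(repr=False)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]


def interpupil_distance(eyes: EyePair) -> float:
    """Euclidean distance between the two eye centers, in pixels."""
    (lx, ly), (rx, ry) = eyes.left, eyes.right
    return math.hypot(rx - lx, ry - ly)


def rotation_matrix(eyes: EyePair) -> AlignmentTransform:
    """Rotation about the eye midpoint that describes the eye tilt.

    theta = atan2(ry - ly, rx - lx); atan2 rather than atan so a
    vertical eye pair (rx == lx) is handled without a division by zero
    and agrees with atan((ry-ly)/(rx-lx)) whenever rx > lx.
    """
    (lx, ly), (rx, ry) = eyes.left, eyes.right
    theta = math.atan2(ry - ly, rx - lx)
    x, y = (lx + rx) / 2.0, (ly + ry) / 2.0
    c, s = math.cos(theta), math.sin(theta)
    matrix = np.array(
        [[c, -s, x * (1 - c) + y * s],
         [s, c, y * (1 - c) - x * s]], dtype=float)
    return AlignmentTransform(theta=theta, midpoint=(x, y), matrix=matrix)


def chip_transform(eyes: EyePair, geometry: ChipGeometry | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Affine maps between source-image and chip coordinates.

    Returns (forward, inverse): 2x3 matrices taking source points to
    chip points and chip points to source points respectively.  The
    forward map is the similarity transform rotating by -theta about
    the eye midpoint, scaling by chip_ipd / IPD, and translating the
    midpoint to the chip's canonical eye-midpoint.
    """
    geometry = geometry or ChipGeometry()
    tf = rotation_matrix(eyes)
    ipd = interpupil_distance(eyes)
    scale = geometry.chip_ipd / ipd
    c, s = math.cos(tf.theta), math.sin(tf.theta)
    # rotate by -theta (eyes -> horizontal in y-down coordinates), scale
    rot = scale * np.array([[c, s], [-s, c]])
    (e0, e1) = geometry.chip_eyes
    dst_mid = np.array([(e0[0] + e1[0]) / 2.0, (e0[1] + e1[1]) / 2.0])
    src_mid = np.asarray(tf.midpoint)
    fwd = np.hstack([rot, (dst_mid - rot @ src_mid)[:, None]])
    inv_rot = np.array([[c, -s], [s, c]]) / scale
    inv = np.hstack([inv_rot, (src_mid - inv_rot @ dst_mid)[:, None]])
    return fwd, inv


def transform_points(matrix: np.ndarray, points) -> np.ndarray:
    """Apply a 2x3 affine to an (N, 2) array of (x, y) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ matrix[:, :2].T + matrix[:, 2]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit image to single-channel grayscale (BT.601 luma)."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0]
    if img.ndim == 3 and img.shape[2] == 3:
        luma = (img[:, :, 0] * 0.299 + img[:, :, 1] * 0.587
                + img[:, :, 2] * 0.114)
        return np.round(luma).astype(img.dtype)
    raise ValueError(f"unsupported image shape {img.shape}")


def align_and_chip(image: np.ndarray, eyes: EyePair,
                   geometry: ChipGeometry | None = None,
                   source_image: str = "", source_box=None):
    """Extract the canonical face chip around an eye pair.

    Rotation and scaling are composed into one affine warp (a single
    bilinear resampling pass).  If the chip window extends beyond the
    image, edge pixels are replicated and a warning is logged.

    Returns a :class:`sealface.annotations.ChipRecord`.
    """
    from .annotations import ChipRecord  # cycle: ChipRecord stores chips

    geometry = geometry or ChipGeometry()
    ipd = interpupil_distance(eyes)
    if ipd <= 2.0:
        raise ValueError(f"inter-pupil distance {ipd:.2f}px too small to chip")
    gray = to_grayscale(image).astype(np.float32)
    h, w = gray.shape
    size = geometry.chip_size
    _, inv = chip_transform(eyes, geometry)

    u, v = np.meshgrid(np.arange(size, dtype=float),
                       np.arange(size, dtype=float), indexing="xy")
    src = transform_points(inv, np.stack([u.ravel(), v.ravel()], axis=1))
    sx = src[:, 0].reshape(size, size)
    sy = src[:, 1].reshape(size, size)
    if (sx.min() < 0 or sy.min() < 0 or sx.max() > w - 1 or sy.max() > h - 1):
        logger.warning(
            "chip window extends beyond %s image bounds (%dx%d); "
            "edge pixels replicated", source_image or "source", w, h)
    chip = ndimage.map_coordinates(gray, [sy, sx], order=1, mode="nearest")
    chip = np.clip(np.round(chip), 0, 255).astype(np.uint8)

    if source_box is None:
        # bounding box of the warped chip window in the source image
        corners = transform_points(
            inv, [(0, 0), (size - 1, 0), (0, size - 1), (size - 1, size - 1)])
        left, top = corners.min(axis=0)
        right, bottom = corners.max(axis=0)
        source_box = (int(math.floor(left)), int(math.floor(top)),
                      int(math.ceil(right - left)) + 1,
                      int(math.ceil(bottom - top)) + 1)
    return ChipRecord(pixels=chip, source_image=source_image or "<array>",
                      source_box=tuple(source_box), identity=None)
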