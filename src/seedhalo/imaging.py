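"""Core raster types, HSV conversion and spatial calibration.

Images are plain ``numpy`` arrays of shape ``(H, W, 3)`` and dtype ``uint8``
with the origin at the top-left corner (row index increases downward), the
convention shared by scikit-image, imageio and Pillow.  The HSV conversion
reproduces the 8-bit ImageJ scaling: hue, saturation and value are each
mapped to the integer range 0–255 (hue = angle/360·255, truncated), because
plate-analysis threshold presets in this domain are quoted on that scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import imageio.v3 as iio

from .errors import BoundsError, CalibrationError, ImageFormatError

__all__ = [
    "Calibration",
    "CropWindow",
    "HSVPlanes",
    "as_rgb_image",
    "load_image",
    "rgb_to_hsv_planes",
    "hsv_planes_to_rgb",
    "compute_scale",
    "crop",
    "px_area_to_mm2",
    "px_to_mm",
]


class HSVPlanes(NamedTuple):
    """Hue, saturation, value planes, each ``uint8`` in 0–255."""

    h: np.ndarray
    s: np.ndarray
    v: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.h.shape


@dataclass(frozen=True)
class Calibration:
    """Isotropic pixel scale of a plate image.

    Parameters
    ----------
    pixels_per_mm : float
        Number of pixels per millimetre; must be positive and finite.
        Square pixels are assumed.
    """

    pixels_per_mm: float

    def __post_init__(self) -> None:
        ppm = self.pixels_per_mm
        if not np.isfinite(ppm) or ppm <= 0:
            raise CalibrationError(f"pixels_per_mm must be positive and finite, got {ppm!r}")


@dataclass(frozen=True)
class CropWindow:
    """Half-open pixel window [top, bottom) x [left, right)."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (0 <= self.top < self.bottom and 0 <= self.left < self.right):
            raise BoundsError(f"invalid crop window {self}")


def as_rgb_image(pixels: np.ndarray) -> np.ndarray:
    """Validate an array as an 8-bit RGB image and return it as ``uint8``.

    Arrays with an alpha channel have it dropped with a warning; anything
    that is not H x W x 3(+1) raises :class:`ImageFormatError`.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ImageFormatError(f"expected an HxWx3 RGB image, got shape {arr.shape}")
    if arr.shape[2] == 4:
        warnings.warn("alpha channel dropped from RGBA input", stacklevel=2)
        arr = arr[:, :, :3]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ImageFormatError(f"image too small: {arr.shape[:2]}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ImageFormatError(f"expected 8-bit channel intensities, got dtype {arr.dtype}")
    return arr


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an 8-bit RGB array."""
    arr = iio.imread(path)
    if arr.ndim == 2:  # grayscale scan: promote to RGB
        arr = np.stack([arr] * 3, axis=-1)
    return as_rgb_image(arr)


def rgb_to_hsv_planes(image: np.ndarray) -> HSVPlanes:
    """Split an RGB image into 8-bit hue/saturation/value planes.

    Hue is the HSV angle scaled by 255/360 and truncated; saturation is
    ``(1 - min/max)`` scaled by 255 and truncated; value is the channel
    maximum.  Achromatic pixels get ``h = 0`` and ``s = 0``.
    """
    arr = as_rgb_image(image).astype(np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    v = arr.max(axis=-1)
    c = v - arr.min(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, c / v, 0.0)
        hp = np.zeros_like(v)
        safe_c = np.where(c > 0, c, 1.0)
        hp = np.where(v == r, ((g - b) / safe_c) % 6.0, hp)
        hp = np.where((v == g) & (g != r), (b - r) / safe_c + 2.0, hp)
        hp = np.where((v == b) & (b != r) & (b != g), (r - g) / safe_c + 4.0, hp)
    angle = np.where(c > 0, hp * 60.0, 0.0)
    h8 = np.floor(angle / 360.0 * 255.0).astype(np.uint8)
    s8 = np.floor(s * 255.0).astype(np.uint8)
    v8 = v.astype(np.uint8)
    h8 = np.where(c > 0, h8, 0).astype(np.uint8)
    return HSVPlanes(h8, s8, v8)


def hsv_planes_to_rgb(planes: HSVPlanes) -> np.ndarray:
    """Standard inverse of :func:`rgb_to_hsv_planes`.

    Truncated 8-bit hue and saturation are dequantised at the midpoint of
    their quantisation cell before applying the usual HSV-to-RGB formulas,
    so the round trip is exact to within the quantisation step.
    """
    h8, s8, v8 = (np.asarray(p, dtype=np.float64) for p in planes)
    angle = np.minimum((h8 + 0.5) / 255.0 * 360.0, 360.0 - 1e-9)
    s = np.minimum((s8 + 0.5) / 255.0, 1.0)
    s = np.where(s8 == 0, 0.0, s)
    v = v8
    c = v * s
    hp = angle / 60.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    sector = np.floor(hp).astype(int) % 6
    zeros = np.zeros_like(c)
    r1 = np.select([sector == 0, sector == 1, sector == 2, sector == 3, sector == 4], [c, x, zeros, zeros, x], c)
    g1 = np.select([sector == 0, sector == 1, sector == 2, sector == 3, sector == 4], [x, c, c, x, zeros], zeros)
    b1 = np.select([sector == 0, sector == 1, sector == 2, sector == 3, sector == 4], [zeros, zeros, x, c, c], x)
    m = v - c
    rgb = np.stack([r1 + m, g1 + m, b1 + m], axis=-1)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def compute_scale(point_a: Sequence[float], point_b: Sequence[float], known_distance_mm: float) -> Calibration:
    """Derive the pixel scale from two marked points a known distance apart.

    The points are the two extremities of the (square) plate, in pixel
    coordinates; order is irrelevant.
    """
    a = np.asarray(point_a, dtype=float)
    b = np.asarray(point_b, dtype=float)
    if a.shape != (2,) or b.shape != (2,):
        raise CalibrationError("calibration points must be 2-D coordinates")
    if known_distance_mm <= 0 or not np.isfinite(known_distance_mm):
        raise CalibrationError(f"known distance must be positive, got {known_distance_mm!r}")
    dist_px = float(np.hypot(*(a - b)))
    if dist_px == 0:
        raise CalibrationError("calibration points are coincident")
    return Calibration(pixels_per_mm=dist_px / known_distance_mm)


def crop(image: np.ndarray, window: CropWindow) -> np.ndarray:
    """Crop to ``window``; calibration is unaffected by cropping."""
    arr = as_rgb_image(image)
    h, w = arr.shape[:2]
    if window.bottom > h or window.right > w:
        raise BoundsError(f"crop window {window} exceeds image shape {(h, w)}")
    return arr[window.top : window.bottom, window.left : window.right].copy()


def px_area_to_mm2(pixel_count: float, cal: Calibration) -> float:
    """Convert a pixel count to an area in mm²."""
    if pixel_count < 0:
        raise ValueError("pixel count must be non-negative")
    return float(pixel_count) / cal.pixels_per_mm**2


def px_to_mm(length_px: float, cal: Calibration) -> float:
    """Convert a length in pixels to millimetres."""
    return float(length_px) / cal.pixels_per_mm
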