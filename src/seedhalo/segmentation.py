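"""HSV band thresholding of mucilage halos and seeds.

Segmentation works on the 8-bit HSV planes.  A pixel belongs to a target
(mucilage halo or seed) when each of its H, S, V values falls inside the
target's inclusive :class:`ChannelBand`.  The shipped defaults are the
flax (*Linum usitatissimum*) presets of the original supervised workflow:

* mucilage: H in [172, 255], S in [24, 255], V in [85, 255] — the
  purple-pink toluidine-blue-O halo against the light-blue gel;
* seed: V in [0, 70] with H and S passing everything — the dark seed body
  is isolated by brightness alone.

An iterative-intermeans (IsoData) threshold suggester is provided for
recalibrating the bands on new species or imaging setups; it is advisory
and the defaults apply unless explicitly requested.
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import DegenerateHistogramError, ImageFormatError, ParameterError
from .imaging import HSVPlanes, as_rgb_image, rgb_to_hsv_planes

__all__ = [
    "ChannelBand",
    "SegmentationParams",
    "default_params",
    "band_mask",
    "isodata_threshold",
    "suggest_params",
    "segment_mucilage",
    "segment_seeds",
    "fill_holes",
    "load_presets",
    "TARGETS",
]

TARGETS = ("mucilage", "seed")


class ChannelBand(NamedTuple):
    """Inclusive intensity band [low, high] on one 8-bit channel."""

    low: int
    high: int

    def validate(self) -> "ChannelBand":
        if not (0 <= self.low <= self.high <= 255):
            raise ParameterError(f"invalid channel band {self}")
        return self

    def contains(self, plane: np.ndarray) -> np.ndarray:
        return (plane >= self.low) & (plane <= self.high)


@dataclass(frozen=True)
class SegmentationParams:
    """Per-target HSV threshold bands."""

    h_band: ChannelBand
    s_band: ChannelBand
    v_band: ChannelBand
    target: str

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ParameterError(f"unknown segmentation target {self.target!r}; expected one of {TARGETS}")
        for band in (self.h_band, self.s_band, self.v_band):
            ChannelBand(*band).validate()


#: Flax defaults.  The quoted single numbers (mucilage 172/24/85, seed
#: 255/255/70) are the non-trivial bound of each band; the other end is the
#: channel extreme.  Seed H/S "255" means the pass-all band [0, 255].
_DEFAULTS = {
    "mucilage": SegmentationParams(
        h_band=ChannelBand(172, 255),
        s_band=ChannelBand(24, 255),
        v_band=ChannelBand(85, 255),
        target="mucilage",
    ),
    "seed": SegmentationParams(
        h_band=ChannelBand(0, 255),
        s_band=ChannelBand(0, 255),
        v_band=ChannelBand(0, 70),
        target="seed",
    ),
}


def default_params(target: str) -> SegmentationParams:
    """Return the shipped flax threshold bands for ``target``."""
    try:
        return _DEFAULTS[target]
    except KeyError:
        raise ParameterError(f"unknown segmentation target {target!r}; expected one of {TARGETS}") from None


def band_mask(planes: HSVPlanes, params: SegmentationParams) -> np.ndarray:
    """Boolean mask of pixels inside all three HSV bands (inclusive)."""
    h, s, v = planes.h, planes.s, planes.v
    if not (h.shape == s.shape == v.shape):
        raise ImageFormatError("HSV planes have mismatched shapes")
    return params.h_band.contains(h) & params.s_band.contains(s) & params.v_band.contains(v)


def isodata_threshold(histogram: np.ndarray) -> int:
    """Iterative-intermeans (IsoData) threshold of a 256-bin histogram.

    Starting from the intensity bisecting the histogram mass, iterate
    ``T <- round((mean of intensities <= T + mean of intensities > T) / 2)``
    (ties round half up) until ``T`` is stable.  The result splits the
    histogram into a dark and a bright class whose means straddle ``T``.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are populated (no two classes exist).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has fewer than two populated bins")

    levels = np.arange(256, dtype=np.float64)
    csum = np.cumsum(hist)
    cmoment = np.cumsum(levels * hist)
    total, moment = csum[-1], cmoment[-1]

    t = int(np.searchsorted(csum, total / 2.0))
    lo_bin = int(np.flatnonzero(hist)[0])
    hi_bin = int(np.flatnonzero(hist)[-1])
    seen: set[int] = set()
    while True:
        t = min(max(t, lo_bin), hi_bin - 1)  # keep both classes populated
        n_lo = csum[t]
        mean_lo = cmoment[t] / n_lo
        mean_hi = (moment - cmoment[t]) / (total - n_lo)
        t_next = int(np.floor((mean_lo + mean_hi) / 2.0 + 0.5))
        if t_next == t:
            return t
        if t_next in seen:  # 2-cycle guard; pick the current iterate
            return t
        seen.add(t)
        t = t_next


def suggest_params(planes: HSVPlanes, target: str) -> SegmentationParams:
    """Suggest threshold bands for ``target`` from the image's own histograms.

    Each channel gets an iterative-intermeans threshold, mapped onto the
    band geometry of the target: mucilage bands keep the upper class
    (low = T + 1), the seed V band keeps the dark class (high = T).  Seed
    H and S stay pass-all.  On a degenerate channel histogram the shipped
    defaults are returned with a warning — the suggester is advisory.
    """
    base = default_params(target)
    try:
        thresholds = {}
        for name, plane in zip("hsv", planes):
            hist = np.bincount(np.asarray(plane, dtype=np.uint8).ravel(), minlength=256)
            thresholds[name] = isodata_threshold(hist)
    except DegenerateHistogramError:
        warnings.warn(
            f"degenerate channel histogram; falling back to default {target} thresholds",
            stacklevel=2,
        )
        return base

    if target == "mucilage":
        return replace(
            base,
            h_band=ChannelBand(min(thresholds["h"] + 1, 255), 255),
            s_band=ChannelBand(min(thresholds["s"] + 1, 255), 255),
            v_band=ChannelBand(min(thresholds["v"] + 1, 255), 255),
        )
    return replace(base, v_band=ChannelBand(0, thresholds["v"]))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed background regions of a binary mask.

    Foreground is treated as 8-connected and background as 4-connected (the
    standard dual pairing); a background region counts as a hole when it has
    no 4-connected path to the image border.
    """
    # scipy's default cross-shaped structure gives 4-connected background
    # flood fill from the border, i.e. exactly the dual pairing wanted here.
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def segment_mucilage(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Binary mask of soluble-mucilage halos, hole-filled.

    The measured halo area deliberately includes the pixels occupied by the
    seed inside it: the halo region is every pixel contained inside the
    perimeter drawn by the stained-mucilage outline, so each halo comes out
    simply connected.
    """
    if params is None:
        params = default_params("mucilage")
    if params.target != "mucilage":
        raise ParameterError(f"expected mucilage params, got target {params.target!r}")
    planes = rgb_to_hsv_planes(as_rgb_image(image))
    return fill_holes(band_mask(planes, params))


def segment_seeds(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Binary mask of seed bodies, hole-filled (specular highlights closed)."""
    if params is None:
        params = default_params("seed")
    if params.target != "seed":
        raise ParameterError(f"expected seed params, got target {params.target!r}")
    planes = rgb_to_hsv_planes(as_rgb_image(image))
    return fill_holes(band_mask(planes, params))


def load_presets(path=None) -> dict[str, dict]:
    """Load per-species threshold presets from a plain-text config.

    Without ``path`` the packaged ``presets.ini`` is used.  Each section is
    a species and yields ``{"mucilage": SegmentationParams, "seed":
    SegmentationParams, "mucilage_area_mm2": (lo, hi), "seed_area_mm2":
    (lo, hi)}``.
    """
    parser = configparser.ConfigParser()
    if path is None:
        text = resources.files("seedhalo").joinpath("presets.ini").read_text()
        parser.read_string(text)
    else:
        with open(path) as fh:
            parser.read_file(fh)
    presets: dict[str, dict] = {}
    for species in parser.sections():
        sec = parser[species]

        def band(key: str) -> ChannelBand:
            lo, hi = (int(x) for x in sec[key].split(","))
            return ChannelBand(lo, hi).validate()

        def pair(key: str) -> tuple[float, float]:
            lo, hi = (float(x) for x in sec[key].split(","))
            return lo, hi

        presets[species] = {
            "mucilage": SegmentationParams(
                band("mucilage_h"), band("mucilage_s"), band("mucilage_v"), target="mucilage"
            ),
            "seed": SegmentationParams(band("seed_h"), band("seed_s"), band("seed_v"), target="seed"),
            "mucilage_area_mm2": pair("mucilage_area_mm2"),
            "seed_area_mm2": pair("seed_area_mm2"),
        }
    return presets
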