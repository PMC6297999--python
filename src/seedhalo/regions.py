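"""Connected-component labeling in reading order and area filtering.

Objects (seeds, halos) are 8-connected components of a binary mask and are
numbered line by line from the top to the bottom of the image: component k
is the k-th component encountered when scanning rows top-down (ties within
a row broken left-to-right, on each component's topmost-then-leftmost
pixel).  This reading order is what makes rank matching of seeds to halos
on diagonally sown plates work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .imaging import Calibration, px_area_to_mm2

__all__ = ["LabeledRegions", "AreaRangeFilter", "label_components", "filter_by_area", "flag_border_regions"]

logger = logging.getLogger("seedhalo")

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class LabeledRegions:
    """Integer-labeled mask: 0 = background, 1..count = objects in reading order.

    ``order_index[k - 1]`` is the (row, column) anchor (topmost, then
    leftmost pixel) of label ``k``; anchors are strictly increasing in
    raster order.
    """

    labels: np.ndarray
    count: int
    order_index: list[tuple[int, int]] = field(default_factory=list)

    def areas_px(self) -> np.ndarray:
        """Pixel count per label, index 0 unused."""
        return np.bincount(self.labels.ravel(), minlength=self.count + 1)

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class AreaRangeFilter:
    """Inclusive physical-area window [min_mm2, max_mm2] an object must fit."""

    min_mm2: float
    max_mm2: float

    def __post_init__(self) -> None:
        if not (0 <= self.min_mm2 < self.max_mm2):
            raise ParameterError(f"invalid area filter {self}")


def label_components(mask: np.ndarray) -> LabeledRegions:
    """Label 8-connected components of ``mask`` in top-to-bottom reading order."""
    mask = np.asarray(mask, dtype=bool)
    raw, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return LabeledRegions(labels=raw.astype(np.int32), count=0, order_index=[])

    # Anchor of each raw label = its first pixel in raster order.
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier raster positions overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")  # raw labels sorted by anchor

    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1, dtype=np.int32)
    labels = remap[raw]
    w = mask.shape[1]
    anchors = [(int(first[o + 1] // w), int(first[o + 1] % w)) for o in order]
    return LabeledRegions(labels=labels, count=int(n), order_index=anchors)


def filter_by_area(regions: LabeledRegions, filt: AreaRangeFilter, cal: Calibration) -> LabeledRegions:
    """Drop components whose physical area falls outside the filter window.

    Merged halos (two objects fused on the gel) exceed the upper bound and
    are deleted rather than split; dust specks fall below the lower bound.
    Survivors are renumbered 1..m preserving reading order; every removal is
    logged with its original label and area.
    """
    if regions.count == 0:
        return regions
    areas_px = regions.areas_px()
    keep = np.zeros(regions.count + 1, dtype=bool)
    for lab in range(1, regions.count + 1):
        area = px_area_to_mm2(int(areas_px[lab]), cal)
        if filt.min_mm2 <= area <= filt.max_mm2:
            keep[lab] = True
        else:
            reason = "below minimum" if area < filt.min_mm2 else "above maximum (merged objects?)"
            logger.warning(
                "removed region %d: area %.2f mm² %s [%.1f, %.1f]",
                lab, area, reason, filt.min_mm2, filt.max_mm2,
            )
    remap = np.zeros(regions.count + 1, dtype=np.int32)
    survivors = np.flatnonzero(keep)
    remap[survivors] = np.arange(1, survivors.size + 1, dtype=np.int32)
    return LabeledRegions(
        labels=remap[regions.labels],
        count=int(survivors.size),
        order_index=[regions.order_index[lab - 1] for lab in survivors],
    )


def flag_border_regions(regions: LabeledRegions) -> set[int]:
    """Labels with at least one pixel on the image border.

    Border-touching objects are typically clipped by the crop window and
    should be inspected (or deleted via the CLI option) rather than trusted.
    """
    lab = regions.labels
    if regions.count == 0:
        return set()
    border = np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    return set(int(x) for x in np.unique(border) if x != 0)
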