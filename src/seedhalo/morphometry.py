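"""Calibrated shape descriptors for labeled regions.

Each labeled object gets the canonical 11-descriptor record used for seed
and mucilage phenotyping: area, perimeter, circularity, maximum and minimum
Feret diameter, Feret angle, solidity, convex area, aspect ratio and the
centroid coordinates.  All lengths are in millimetres and areas in mm²
via the plate calibration.

Estimator choices
-----------------
* Area is the pixel count (scaled) — not an idealised pi·r² formula.
* Perimeter is the 8-connected chain code of the traced outer boundary
  (axis steps weigh 1, diagonal steps sqrt(2)) multiplied by the classical
  0.948 isotropy correction, which removes the systematic ~5% over-estimate
  of chain codes on smooth contours.  The raw chain length is available via
  :func:`chain_code_length` or ``corrected=False``.
* Circularity = 4*pi*area/perimeter², clipped at 1.0: digitisation can push
  raw values slightly above 1 and the descriptor's range is 0.0–1.0, with
  1.0 meaning a perfectly round object.
* Convex area is the area of the convex hull of the pixel *squares*
  (pixel centers dilated by 0.5 px), so convex_area >= area always holds
  and solidity = area/convex_area is exactly 1.0 for convex digital shapes.
* Feret diameters come from the convex hull of pixel centers: the maximum
  pairwise vertex distance and the minimal caliper width over hull edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import EmptyRegionError, UndefinedMetricError
from .imaging import Calibration, px_area_to_mm2, px_to_mm
from .regions import LabeledRegions

__all__ = [
    "RegionMetrics",
    "CHAIN_CORRECTION",
    "chain_code_length",
    "region_area",
    "region_perimeter",
    "circularity",
    "feret",
    "solidity",
    "measure_all",
]

#: Isotropy correction for 8-connected chain-code boundary length.
CHAIN_CORRECTION = 0.948

# Moore neighbourhood, clockwise starting at N (row decreasing).
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass(frozen=True)
class RegionMetrics:
    """Morphometric descriptor record for one labeled object (mm-based units)."""

    label: int
    area_mm2: float
    perimeter_mm: float
    circularity: float
    feret_mm: float
    min_feret_mm: float
    feret_angle_deg: float
    solidity: float
    convex_area_mm2: float
    aspect_ratio: float
    centroid_x_mm: float
    centroid_y_mm: float


def _trace_chain(mask: np.ndarray) -> list[int]:
    """Freeman chain code of the outer boundary of the (single) component.

    Moore-neighbour tracing from the raster-first pixel; returns [] for a
    single-pixel component (degenerate polygon).
    """
    m = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    m[1:-1, 1:-1] = mask
    ys, xs = np.nonzero(m)
    if ys.size == 0:
        raise EmptyRegionError("cannot trace an empty mask")
    if ys.size == 1:
        return []
    start = (int(ys[0]), int(xs[0]))
    chain: list[int] = []
    cur = start
    backtrack = 6  # entered scanning left-to-right: previous pixel is to the west
    while True:
        for k in range(8):
            d = (backtrack + 1 + k) % 8
            ny, nx = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if m[ny, nx]:
                break
        else:  # isolated pixel (cannot happen: size > 1 and 8-connected)
            return []
        # Jacob's stopping criterion: about to leave the start pixel in the
        # same direction as the very first move -> the trace would repeat.
        if cur == start and chain and d == chain[0]:
            break
        chain.append(d)
        cur = (ny, nx)
        backtrack = (d + 4) % 8
        if len(chain) > 8 * ys.size:  # safety cap for pathological masks
            break
    return chain


def chain_code_length(mask: np.ndarray) -> float:
    """Raw chain-code boundary length in pixels (1 per axis step, sqrt(2) per diagonal)."""
    chain = _trace_chain(np.asarray(mask, dtype=bool))
    if not chain:
        return 0.0
    n_diag = sum(1 for d in chain if d % 2)
    return (len(chain) - n_diag) + n_diag * math.sqrt(2.0)


def region_area(mask: np.ndarray, cal: Calibration) -> float:
    """Projected 2-D area: pixel count converted to mm²."""
    count = int(np.count_nonzero(mask))
    if count == 0:
        raise EmptyRegionError("empty region has no area")
    return px_area_to_mm2(count, cal)


def region_perimeter(mask: np.ndarray, cal: Calibration, corrected: bool = True) -> float:
    """Length of the traced outer boundary in mm.

    ``corrected=True`` applies the 0.948 chain-code isotropy correction;
    ``corrected=False`` returns the raw chain length.
    """
    length = chain_code_length(mask)
    if corrected:
        length *= CHAIN_CORRECTION
    return px_to_mm(length, cal)


def circularity(area_mm2: float, perimeter_mm: float) -> float:
    """4*pi*area/perimeter², clipped at 1.0 (1.0 = perfectly round)."""
    if perimeter_mm <= 0:
        raise UndefinedMetricError("circularity undefined for zero perimeter")
    return min(1.0, 4.0 * math.pi * area_mm2 / perimeter_mm**2)


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices of an (n, 2) point set; falls back on degeneracy."""
    pts = np.unique(points, axis=0).astype(np.float64)
    if pts.shape[0] <= 2:
        return pts
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except QhullError:  # collinear points
        # order along the dominant axis and keep the extremes
        axis = int(np.argmax(pts.max(axis=0) - pts.min(axis=0)))
        order = np.argsort(pts[:, axis])
        return pts[order[[0, -1]]]


def feret(mask: np.ndarray, cal: Calibration) -> tuple[float, float, float]:
    """(max Feret, min Feret, Feret angle in degrees) of a component.

    Max Feret is the longest distance between two pixel centers (attained
    on hull vertices); min Feret is the minimal caliper width over hull
    edge orientations; the angle of the max-Feret chord is measured
    counter-clockwise from the image x-axis, in [0, 180).
    """
    coords = np.argwhere(np.asarray(mask, dtype=bool))  # (row, col)
    if coords.shape[0] == 0:
        raise EmptyRegionError("empty region has no Feret diameter")
    if coords.shape[0] == 1:
        return 0.0, 0.0, 0.0
    verts = _hull_vertices(coords)
    diff = verts[:, None, :] - verts[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    fer_px = math.sqrt(float(d2[i, j]))
    drow = verts[j, 0] - verts[i, 0]
    dcol = verts[j, 1] - verts[i, 1]
    angle = math.degrees(math.atan2(-drow, dcol)) % 180.0

    if verts.shape[0] == 2:
        min_fer_px = 0.0
    else:
        # minimal caliper width: for each hull edge, the farthest vertex distance
        min_fer_px = math.inf
        n = verts.shape[0]
        for k in range(n):
            p, q = verts[k], verts[(k + 1) % n]
            edge = q - p
            norm = math.hypot(*edge)
            if norm == 0:
                continue
            rel = verts - p
            dist = np.abs(edge[0] * rel[:, 1] - edge[1] * rel[:, 0]) / norm
            min_fer_px = min(min_fer_px, float(dist.max()))
    return px_to_mm(fer_px, cal), px_to_mm(min_fer_px, cal), angle


def solidity(mask: np.ndarray, cal: Calibration) -> tuple[float, float]:
    """(solidity, convex area in mm²) of a component.

    Convex area is the shoelace area of the hull of the pixel squares
    (centers dilated by 0.5 px in each direction), guaranteeing
    convex_area >= pixel-count area; solidity is clipped at 1.0.
    """
    coords = np.argwhere(np.asarray(mask, dtype=bool)).astype(np.float64)
    if coords.shape[0] == 0:
        raise EmptyRegionError("empty region has no solidity")
    area_px = float(coords.shape[0])
    offsets = np.array([(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)])
    corners = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    verts = _hull_vertices(corners)
    if verts.shape[0] < 3:
        return 1.0, px_area_to_mm2(area_px, cal)  # degenerate hull: define convex
    x, y = verts[:, 1], verts[:, 0]
    hull_area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    sol = min(1.0, area_px / hull_area) if hull_area > 0 else 1.0
    return sol, px_area_to_mm2(hull_area, cal)


def _measure_one(mask: np.ndarray, label: int, cal: Calibration, row0: int, col0: int) -> RegionMetrics:
    area = region_area(mask, cal)
    perim = region_perimeter(mask, cal)
    circ = circularity(area, perim) if perim > 0 else 1.0
    fer, min_fer, angle = feret(mask, cal)
    sol, convex_area = solidity(mask, cal)
    coords = np.argwhere(mask)
    cy = (coords[:, 0].mean() + row0) / cal.pixels_per_mm
    cx = (coords[:, 1].mean() + col0) / cal.pixels_per_mm
    aspect = fer / min_fer if min_fer > 0 else 1.0
    return RegionMetrics(
        label=label,
        area_mm2=area,
        perimeter_mm=perim,
        circularity=circ,
        feret_mm=fer,
        min_feret_mm=min_fer,
        feret_angle_deg=angle,
        solidity=sol,
        convex_area_mm2=convex_area,
        aspect_ratio=aspect,
        centroid_x_mm=cx,
        centroid_y_mm=cy,
    )


def measure_all(regions: LabeledRegions, cal: Calibration) -> list[RegionMetrics]:
    """One :class:`RegionMetrics` per label, in label (reading) order."""
    if regions.count == 0:
        return []
    slices = ndimage.find_objects(regions.labels)
    out: list[RegionMetrics] = []
    for label in range(1, regions.count + 1):
        sl = slices[label - 1]
        sub = regions.labels[sl] == label
        out.append(_measure_one(sub, label, cal, sl[0].start, sl[1].start))
    return out
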