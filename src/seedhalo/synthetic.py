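"""Synthetic stained-plate images with analytic ground truth.

The generator emulates a scanned square agarose plate from the staining
assay: a light-blue gel background, dark elliptical seeds, and concentric
purple-pink halos of released soluble mucilage around them, optionally with
Gaussian sensor noise.  Every geometric parameter is known, so each plate
comes with a ground-truth table of analytic areas, perimeters (Ramanujan's
ellipse approximation for seeds), Feret diameters, circularities and the
true seed-halo pairing — the oracle for end-to-end tests.

The default palette is chosen so that the shipped flax HSV bands segment
the rendered objects: background (190, 215, 235) falls outside the
mucilage hue band, seed (60, 40, 30) sits below the seed brightness cutoff,
and the halo gradient (200, 120, 180) -> (215, 150, 200) stays inside all
three mucilage bands.  These are package constants of the renderer, not
measured dye colours.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["PlateSpec", "GroundTruth", "generate_plate", "generate_regression_suite"]

BACKGROUND_RGB = (190, 215, 235)
SEED_RGB = (60, 40, 30)
HALO_INNER_RGB = (200, 120, 180)
HALO_OUTER_RGB = (215, 150, 200)


@dataclass(frozen=True)
class PlateSpec:
    """Recipe for one synthetic plate.

    ``sowing="diagonal"`` places centers strictly monotonically in both row
    and column (the layout that makes rank matching exact); ``"jittered"``
    scatters seeds on a shuffled grid.  The plate side is computed from the
    seed count and halo sizes unless ``image_shape`` is given.
    """

    n_seeds: int = 10
    pixels_per_mm: float = 8.0
    sowing: str = "diagonal"
    noise_sigma: float = 0.0
    rng_seed: int = 0
    image_shape: tuple[int, int] | None = None
    seed_semi_major_mm: tuple[float, float] = (2.0, 2.6)
    seed_semi_minor_mm: tuple[float, float] = (1.0, 1.3)
    halo_radius_mm: tuple[float, float] = (3.5, 6.0)
    margin_mm: float = 2.0
    gradient: bool = True
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    seed_rgb: tuple[int, int, int] = SEED_RGB
    halo_inner_rgb: tuple[int, int, int] = HALO_INNER_RGB
    halo_outer_rgb: tuple[int, int, int] = HALO_OUTER_RGB
    overlap_pair: bool = False
    border_touch: bool = False
    mucilage_free: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.sowing not in ("diagonal", "jittered"):
            raise ValueError(f"unknown sowing mode {self.sowing!r}")
        if self.halo_radius_mm[0] <= self.seed_semi_major_mm[1]:
            raise ValueError("halo radius must exceed the seed semi-major axis")


@dataclass
class GroundTruth:
    """Analytic per-object truth table (one row per sown seed).

    Columns include center positions (px), seed ellipse parameters, halo
    radius, and closed-form area/perimeter/Feret/circularity/solidity for
    seed and halo plus the true AreaM/AreaS ratio.  Seed perimeters use
    Ramanujan's approximation (relative error < 1e-4 for these axis
    ratios).  Rows are in sowing order, which is the true pairing.
    """

    objects: pd.DataFrame
    pixels_per_mm: float

    def to_csv(self, path) -> None:
        self.objects.to_csv(path, index=False, float_format="%.6f")


def _ramanujan_perimeter(a: float, b: float) -> float:
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def _auto_layout(spec: PlateSpec, rng: np.random.Generator):
    """Draw per-seed geometry and place centers; returns (centers_mm, a, b, theta, R, side_mm)."""
    n = spec.n_seeds
    a = rng.uniform(*spec.seed_semi_major_mm, size=n)
    b = rng.uniform(*spec.seed_semi_minor_mm, size=n)
    theta = rng.uniform(0.0, 180.0, size=n)
    radius = rng.uniform(*spec.halo_radius_mm, size=n)

    if spec.overlap_pair:
        # two large halos (~177 mm² each) whose centers sit closer than the
        # sum of radii: the rendered union (~340 mm²) exceeds the default
        # 315 mm² ceiling and exercises the merged-halo deletion filter
        radius[:2] = 7.5

    r_max = float(radius.max())
    margin = spec.margin_mm
    if spec.sowing == "diagonal":
        step = 2.0 * r_max + margin  # center spacing along the diagonal
        d = step / math.sqrt(2.0)
        offset = r_max + margin
        rows = offset + d * np.arange(n)
        cols = offset + d * np.arange(n)
        side = offset * 2.0 + d * (n - 1)
        if spec.overlap_pair and n >= 2:
            # pull seed 2 toward seed 1 so the two halos merge
            rows[1] = rows[0] + 14.0 / math.sqrt(2.0)
            cols[1] = cols[0] + 14.0 / math.sqrt(2.0)
    else:
        cell = 2.0 * r_max + 2.0 * margin
        g = math.ceil(math.sqrt(n))
        side = g * cell + 2.0 * margin
        slots = [(i, j) for i in range(g) for j in range(g)]
        rng.shuffle(slots)
        rows = np.empty(n)
        cols = np.empty(n)
        for k, (i, j) in enumerate(slots[:n]):
            rows[k] = margin + (i + 0.5) * cell + rng.uniform(-margin / 2, margin / 2)
            cols[k] = margin + (j + 0.5) * cell + rng.uniform(-margin / 2, margin / 2)
    if spec.border_touch:
        cols[-1] = side - radius[-1] / 2.0  # halo crosses the right edge
    return np.stack([rows, cols], axis=1), a, b, theta, radius, side


def generate_plate(spec: PlateSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one plate; deterministic for a fixed ``rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    centers_mm, a_mm, b_mm, theta_deg, radius_mm, side_mm = _auto_layout(spec, rng)
    ppmm = spec.pixels_per_mm
    if spec.image_shape is not None:
        shape = spec.image_shape
    else:
        side_px = int(math.ceil(side_mm * ppmm))
        shape = (side_px, side_px)

    img = np.empty(shape + (3,), dtype=np.float64)
    img[:] = spec.background_rgb
    inner = np.asarray(spec.halo_inner_rgb, dtype=np.float64)
    outer = np.asarray(spec.halo_outer_rgb, dtype=np.float64)

    def window(cy, cx, r):
        r0 = max(int(math.floor(cy - r)), 0)
        r1 = min(int(math.ceil(cy + r)) + 1, shape[0])
        c0 = max(int(math.floor(cx - r)), 0)
        c1 = min(int(math.ceil(cx + r)) + 1, shape[1])
        return r0, r1, c0, c1

    # halos first (seeds are drawn on top of them)
    for k in range(spec.n_seeds):
        if (k + 1) in spec.mucilage_free:
            continue
        cy, cx = centers_mm[k] * ppmm
        r_px = radius_mm[k] * ppmm
        r0, r1, c0, c1 = window(cy, cx, r_px)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dist = np.hypot(yy - cy, xx - cx)
        mask = dist <= r_px
        if spec.gradient:
            t = np.clip(dist / r_px, 0.0, 1.0)[mask, None]
            img[r0:r1, c0:c1][mask] = inner + (outer - inner) * t
        else:
            img[r0:r1, c0:c1][mask] = inner

    for k in range(spec.n_seeds):
        cy, cx = centers_mm[k] * ppmm
        a_px, b_px = a_mm[k] * ppmm, b_mm[k] * ppmm
        th = math.radians(theta_deg[k])
        r0, r1, c0, c1 = window(cy, cx, a_px)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy, dx = yy - cy, xx - cx
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        mask = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
        img[r0:r1, c0:c1][mask] = spec.seed_rgb

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    rows = []
    for k in range(spec.n_seeds):
        a, b, radius = float(a_mm[k]), float(b_mm[k]), float(radius_mm[k])
        has_halo = (k + 1) not in spec.mucilage_free
        seed_area = math.pi * a * b
        seed_perim = _ramanujan_perimeter(a, b)
        halo_area = math.pi * radius**2 if has_halo else math.nan
        rows.append(
            {
                "sowing_order": k + 1,
                "center_row_px": centers_mm[k, 0] * ppmm,
                "center_col_px": centers_mm[k, 1] * ppmm,
                "seed_semi_major_mm": a,
                "seed_semi_minor_mm": b,
                "seed_angle_deg": float(theta_deg[k]),
                "halo_radius_mm": radius if has_halo else 0.0,
                "seed_area_mm2": seed_area,
                "seed_perimeter_mm": seed_perim,
                "seed_feret_mm": 2.0 * a,
                "seed_circularity": min(1.0, 4.0 * math.pi * seed_area / seed_perim**2),
                "seed_solidity": 1.0,
                "halo_area_mm2": halo_area,
                "halo_perimeter_mm": 2.0 * math.pi * radius if has_halo else math.nan,
                "halo_feret_mm": 2.0 * radius if has_halo else math.nan,
                "halo_circularity": 1.0 if has_halo else math.nan,
                "halo_solidity": 1.0 if has_halo else math.nan,
                "ratio_area": halo_area / seed_area if has_halo else math.nan,
            }
        )
    truth = GroundTruth(objects=pd.DataFrame(rows), pixels_per_mm=ppmm)
    return image, truth


def _suite_specs() -> dict[str, PlateSpec]:
    small = dict(pixels_per_mm=20.0)
    return {
        "clean": PlateSpec(n_seeds=8, rng_seed=101),
        "noisy": PlateSpec(n_seeds=8, noise_sigma=8.0, rng_seed=102),
        "merged_halo": PlateSpec(n_seeds=4, overlap_pair=True, rng_seed=103),
        "border_touching": PlateSpec(n_seeds=5, border_touch=True, rng_seed=104),
        "no_mucilage_seed": PlateSpec(n_seeds=6, mucilage_free=(3,), rng_seed=105),
        "species_linum": PlateSpec(n_seeds=6, rng_seed=106),
        "species_arabidopsis": PlateSpec(
            n_seeds=6, rng_seed=107, seed_semi_major_mm=(0.23, 0.27),
            seed_semi_minor_mm=(0.13, 0.17), halo_radius_mm=(0.7, 1.1),
            margin_mm=0.5, pixels_per_mm=40.0,
        ),
        "species_camelina": PlateSpec(
            n_seeds=6, rng_seed=108, seed_semi_major_mm=(0.9, 1.2),
            seed_semi_minor_mm=(0.45, 0.6), halo_radius_mm=(1.6, 2.4),
            margin_mm=1.0, **small,
        ),
        "species_plantago": PlateSpec(
            n_seeds=6, rng_seed=109, seed_semi_major_mm=(0.7, 0.9),
            seed_semi_minor_mm=(0.35, 0.5), halo_radius_mm=(1.4, 2.0),
            margin_mm=1.0, **small,
        ),
        "species_capsella": PlateSpec(
            n_seeds=6, rng_seed=110, seed_semi_major_mm=(0.4, 0.55),
            seed_semi_minor_mm=(0.2, 0.3), halo_radius_mm=(0.9, 1.4),
            margin_mm=0.8, **small,
        ),
    }


def generate_regression_suite(output_dir) -> pd.DataFrame:
    """Write the fixed scenario plates + ground truth + checksum manifest.

    Returns the manifest (scenario, file, sha256) as a DataFrame; it is
    byte-stable across runs because every plate is seeded.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for name, spec in _suite_specs().items():
        image, truth = generate_plate(spec)
        png = out / f"{name}.png"
        csv = out / f"{name}_truth.csv"
        iio.imwrite(png, image)
        truth.to_csv(csv)
        for path in (png, csv):
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            records.append({"scenario": name, "file": path.name, "sha256": digest})
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.txt", sep="\t", index=False)
    return manifest
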