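"""End-to-end plate analysis: crop, calibrate, segment, measure, match, report.

``run_pipeline`` is a pure function of the input image bytes and the
:class:`RunConfig`: repeated runs write byte-identical CSV tables and
overlay images.  Outputs per run: ``seeds.csv``, ``mucilage.csv``,
``matched.csv``, ``overlay.png`` (a triptych replacing interactive
validation) and ``run.log``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import matching, morphometry, regions, segmentation
from .errors import ConfigError, PipelineError
from .imaging import Calibration, CropWindow, as_rgb_image, compute_scale, crop, load_image
from .matching import MatchResult
from .morphometry import RegionMetrics
from .regions import AreaRangeFilter, LabeledRegions
from .segmentation import SegmentationParams

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "render_overlay", "METRIC_COLUMNS"]

logger = logging.getLogger("seedhalo")

METRIC_COLUMNS = [f.name for f in dataclasses.fields(RegionMetrics)]

# deterministic label tint palette (RGB), cycled by label index
_PALETTE = [
    (230, 60, 60), (60, 160, 60), (60, 90, 220), (220, 160, 40), (150, 60, 200),
    (40, 190, 190), (230, 120, 180), (130, 130, 40), (240, 130, 60), (90, 200, 120),
]


@dataclass
class RunConfig:
    """Everything needed to analyse one plate image.

    Exactly one calibration source must be supplied: either
    ``plate_width_mm`` (the physical width spanned by the full image) or
    ``cal_points = (x1, y1, x2, y2, distance_mm)``.
    """

    image_path: str | Path
    output_dir: str | Path
    plate_width_mm: float | None = None
    cal_points: tuple[float, float, float, float, float] | None = None
    crop_window: CropWindow | None = None
    mucilage_params: SegmentationParams | None = None
    seed_params: SegmentationParams | None = None
    mucilage_area_mm2: tuple[float, float] = (18.0, 315.0)
    seed_area_mm2: tuple[float, float] = (0.5, 50.0)
    match_mode: str = "rank"
    auto_threshold: bool = False
    delete_border: bool = False
    preset: str | None = None

    def __post_init__(self) -> None:
        if (self.plate_width_mm is None) == (self.cal_points is None):
            raise ConfigError("supply exactly one calibration source: plate_width_mm or cal_points")
        if self.match_mode not in ("rank", "containment"):
            raise ConfigError(f"unknown match mode {self.match_mode!r}")


@dataclass
class RunSummary:
    """Counts, warnings and output locations of one pipeline run."""

    n_seeds: int
    n_mucilages: int
    n_pairs: int
    pixels_per_mm: float
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, Path] = field(default_factory=dict)


def _resolve_params(config: RunConfig) -> tuple[SegmentationParams, SegmentationParams, AreaRangeFilter, AreaRangeFilter]:
    muc = config.mucilage_params
    seed = config.seed_params
    muc_area = config.mucilage_area_mm2
    seed_area = config.seed_area_mm2
    if config.preset is not None:
        presets = segmentation.load_presets()
        if config.preset not in presets:
            raise ConfigError(f"unknown preset {config.preset!r}; available: {sorted(presets)}")
        p = presets[config.preset]
        muc = muc or p["mucilage"]
        seed = seed or p["seed"]
        muc_area = p["mucilage_area_mm2"] if muc_area == (18.0, 315.0) else muc_area
        seed_area = p["seed_area_mm2"] if seed_area == (0.5, 50.0) else seed_area
    muc = muc or segmentation.default_params("mucilage")
    seed = seed or segmentation.default_params("seed")
    return muc, seed, AreaRangeFilter(*muc_area), AreaRangeFilter(*seed_area)


def _metrics_frame(metrics: list[RegionMetrics]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for m in metrics], columns=METRIC_COLUMNS)


def _matched_frame(result: MatchResult) -> pd.DataFrame:
    rows = []
    for p in result.pairs:
        row: dict = {"pair_id": p.pair_id}
        row.update({f"seed_{k}": v for k, v in dataclasses.asdict(p.seed).items()})
        row.update({f"mucilage_{k}": v for k, v in dataclasses.asdict(p.mucilage).items()})
        row["ratio_area_m_over_s"] = p.adjusted_mucilage_content
        row["match_mode"] = p.match_mode
        rows.append(row)
    cols = (
        ["pair_id"]
        + [f"seed_{c}" for c in METRIC_COLUMNS]
        + [f"mucilage_{c}" for c in METRIC_COLUMNS]
        + ["ratio_area_m_over_s", "match_mode"]
    )
    return pd.DataFrame(rows, columns=cols)


def render_overlay(
    image: np.ndarray, seed_regions: LabeledRegions, mucilage_regions: LabeledRegions
) -> np.ndarray:
    """Side-by-side triptych: input | tinted mucilage labels | tinted seed labels.

    Each labeled object is tinted with a deterministic per-label colour and
    its number drawn at the centroid, so the pairing can be checked at a
    glance (the static stand-in for an interactive slider view).
    """
    base = as_rgb_image(image)

    def panel(reg: LabeledRegions) -> np.ndarray:
        out = base.astype(np.float64).copy()
        lab = reg.labels
        for k in range(1, reg.count + 1):
            color = np.asarray(_PALETTE[(k - 1) % len(_PALETTE)], dtype=np.float64)
            mask = lab == k
            out[mask] = 0.45 * out[mask] + 0.55 * color
        pil = Image.fromarray(np.clip(np.round(out), 0, 255).astype(np.uint8))
        draw = ImageDraw.Draw(pil)
        for k in range(1, reg.count + 1):
            coords = np.argwhere(lab == k)
            cy, cx = coords.mean(axis=0)
            draw.text((float(cx), float(cy)), str(k), fill=(255, 255, 255), anchor="mm")
        return np.asarray(pil)

    return np.concatenate([base, panel(mucilage_regions), panel(seed_regions)], axis=1)


def run_pipeline(config: RunConfig) -> RunSummary:
    """Analyse one plate image and write all result files.

    Raises :class:`PipelineError` when segmentation finds no seed or no
    mucilage object — an empty result almost always means a wrong
    calibration, crop or threshold, not an empty plate.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out_dir, log_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path, log_path: Path) -> RunSummary:
    image = load_image(config.image_path)
    if config.cal_points is not None:
        x1, y1, x2, y2, dist_mm = config.cal_points
        cal = compute_scale((x1, y1), (x2, y2), dist_mm)
    else:
        cal = Calibration(pixels_per_mm=image.shape[1] / config.plate_width_mm)
    logger.info("calibration: %.4f px/mm", cal.pixels_per_mm)

    if config.crop_window is not None:
        image = crop(image, config.crop_window)
        logger.info("cropped to %s", config.crop_window)

    muc_params, seed_params, muc_filter, seed_filter = _resolve_params(config)
    if config.auto_threshold:
        from .imaging import rgb_to_hsv_planes

        planes = rgb_to_hsv_planes(image)
        muc_params = segmentation.suggest_params(planes, "mucilage")
        seed_params = segmentation.suggest_params(planes, "seed")
        logger.info("auto thresholds: mucilage=%s seed=%s", muc_params, seed_params)

    muc_mask = segmentation.segment_mucilage(image, muc_params)
    seed_mask = segmentation.segment_seeds(image, seed_params)

    muc_regions = regions.filter_by_area(regions.label_components(muc_mask), muc_filter, cal)
    seed_regions = regions.filter_by_area(regions.label_components(seed_mask), seed_filter, cal)

    warnings_list: list[str] = []
    for name, reg in (("mucilage", muc_regions), ("seed", seed_regions)):
        border = regions.flag_border_regions(reg)
        if border:
            msg = f"{name} regions touching the image border: {sorted(border)}"
            warnings_list.append(msg)
            logger.warning(msg)
            if config.delete_border:
                keep = np.isin(reg.labels, sorted(set(range(1, reg.count + 1)) - border))
                relabeled = regions.label_components(reg.labels.astype(bool) & keep)
                if name == "mucilage":
                    muc_regions = relabeled
                else:
                    seed_regions = relabeled
                logger.info("deleted %d border-touching %s regions", len(border), name)

    if seed_regions.count == 0 or muc_regions.count == 0:
        raise PipelineError(
            f"empty segmentation (seeds: {seed_regions.count}, mucilages: {muc_regions.count}); "
            "check calibration, crop window and threshold bands"
        )

    seed_metrics = morphometry.measure_all(seed_regions, cal)
    muc_metrics = morphometry.measure_all(muc_regions, cal)

    if config.match_mode == "rank":
        result = matching.match_by_rank(seed_metrics, muc_metrics)
    else:
        result = matching.match_by_containment(seed_regions, muc_regions, seed_metrics, muc_metrics)
    warnings_list.extend(result.warnings)

    outputs = {
        "seeds": out_dir / "seeds.csv",
        "mucilage": out_dir / "mucilage.csv",
        "matched": out_dir / "matched.csv",
        "overlay": out_dir / "overlay.png",
        "log": log_path,
    }
    _metrics_frame(seed_metrics).to_csv(outputs["seeds"], index=False, float_format="%.4f")
    _metrics_frame(muc_metrics).to_csv(outputs["mucilage"], index=False, float_format="%.4f")
    _matched_frame(result).to_csv(outputs["matched"], index=False, float_format="%.4f")
    iio.imwrite(outputs["overlay"], render_overlay(image, seed_regions, muc_regions))

    logger.info(
        "done: %d seeds, %d mucilages, %d pairs", seed_regions.count, muc_regions.count, len(result.pairs)
    )
    return RunSummary(
        n_seeds=seed_regions.count,
        n_mucilages=muc_regions.count,
        n_pairs=len(result.pairs),
        pixels_per_mm=cal.pixels_per_mm,
        warnings=warnings_list,
        outputs=outputs,
    )
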