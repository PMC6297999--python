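"""Pairing seeds with their mucilage halos and the adjusted mucilage content.

Two strategies are provided:

* **rank** (default): seed k pairs with halo k in reading order.  This is
  exact when seeds are sown on a diagonal, so that both numbering passes
  visit objects in the same order; a halo that swallows its lower-ranked
  neighbour shifts every later rank by one, which is why count mismatches
  are surfaced loudly rather than silently truncated.
* **containment**: a seed pairs with the halo whose region contains the
  seed centroid.  Robust to arbitrary sowing layouts; a halo containing two
  or more seed centroids is reported as merged and yields no pair.

The adjusted mucilage content of a pair is AreaM/AreaS — the halo area
(which includes the pixels under the seed) normalised by the seed area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import UndefinedMetricError
from .morphometry import RegionMetrics
from .regions import LabeledRegions

__all__ = ["MatchedPair", "MatchResult", "match_by_rank", "match_by_containment", "adjusted_content"]

logger = logging.getLogger("seedhalo")


@dataclass(frozen=True)
class MatchedPair:
    """One seed joined to its mucilage halo."""

    pair_id: int
    seed: RegionMetrics
    mucilage: RegionMetrics
    adjusted_mucilage_content: float
    match_mode: Literal["rank", "containment"]


@dataclass
class MatchResult:
    """Pairs plus everything that could not be paired."""

    pairs: list[MatchedPair] = field(default_factory=list)
    unpaired_seeds: list[int] = field(default_factory=list)
    unpaired_mucilages: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def adjusted_content(seed: RegionMetrics, mucilage: RegionMetrics) -> float:
    """AreaM/AreaS for one seed-halo pair."""
    if seed.area_mm2 <= 0:
        raise UndefinedMetricError("adjusted mucilage content undefined for zero seed area")
    return mucilage.area_mm2 / seed.area_mm2


def _pair(pair_id: int, seed: RegionMetrics, muc: RegionMetrics, mode: str) -> MatchedPair:
    return MatchedPair(
        pair_id=pair_id,
        seed=seed,
        mucilage=muc,
        adjusted_mucilage_content=adjusted_content(seed, muc),
        match_mode=mode,  # type: ignore[arg-type]
    )


def match_by_rank(seeds: list[RegionMetrics], mucilages: list[RegionMetrics]) -> MatchResult:
    """Pair seed k with mucilage k (both lists in reading order).

    With unequal counts the surplus objects are reported unpaired and a
    mismatch warning is emitted: a count mismatch usually means some rank
    is off by one (e.g. seed 28 facing mucilage 27), so *all* rank pairs
    after the discrepancy are suspect and should be verified on the overlay.
    """
    result = MatchResult()
    n = min(len(seeds), len(mucilages))
    for k in range(n):
        result.pairs.append(_pair(k + 1, seeds[k], mucilages[k], "rank"))
    if len(seeds) != len(mucilages):
        result.unpaired_seeds = [s.label for s in seeds[n:]]
        result.unpaired_mucilages = [m.label for m in mucilages[n:]]
        msg = (
            f"seed/mucilage count mismatch ({len(seeds)} vs {len(mucilages)}): "
            "rank pairing may be misaligned; check the overlay for mislabeling"
        )
        result.warnings.append(msg)
        logger.warning(msg)
    return result


def match_by_containment(
    seed_regions: LabeledRegions,
    mucilage_regions: LabeledRegions,
    seed_metrics: list[RegionMetrics],
    mucilage_metrics: list[RegionMetrics],
) -> MatchResult:
    """Pair each seed with the halo containing its centroid pixel.

    Both labelings must share the image coordinate frame.  A halo holding
    two or more seed centroids is flagged as merged and contributes no
    pairs; seeds whose centroid lies in no halo (mucilage-free phenotypes)
    are reported unmatched.
    """
    result = MatchResult()
    muc_by_label = {m.label: m for m in mucilage_metrics}
    h, w = seed_regions.labels.shape

    # halo label under each seed centroid
    claims: dict[int, list[RegionMetrics]] = {}
    for seed in seed_metrics:
        sub = seed_regions.labels == seed.label
        coords = np.argwhere(sub)
        cy = int(round(coords[:, 0].mean()))
        cx = int(round(coords[:, 1].mean()))
        cy, cx = min(max(cy, 0), h - 1), min(max(cx, 0), w - 1)
        muc_label = int(mucilage_regions.labels[cy, cx])
        if muc_label == 0:
            result.unpaired_seeds.append(seed.label)
            msg = f"seed {seed.label}: centroid lies in no mucilage region (mucilage-free?)"
            result.warnings.append(msg)
            logger.warning(msg)
        else:
            claims.setdefault(muc_label, []).append(seed)

    pair_id = 0
    for muc_label in sorted(claims):
        claimants = claims[muc_label]
        if len(claimants) > 1:
            msg = (
                f"mucilage {muc_label} contains {len(claimants)} seed centroids "
                f"({[s.label for s in claimants]}): merged halo, no pair emitted"
            )
            result.warnings.append(msg)
            logger.warning(msg)
            result.unpaired_seeds.extend(s.label for s in claimants)
            result.unpaired_mucilages.append(muc_label)
            continue
        pair_id += 1
        result.pairs.append(_pair(pair_id, claimants[0], muc_by_label[muc_label], "containment"))

    matched_mucs = {p.mucilage.label for p in result.pairs} | set(result.unpaired_mucilages)
    result.unpaired_mucilages.extend(m.label for m in mucilage_metrics if m.label not in matched_mucs)
    return result
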