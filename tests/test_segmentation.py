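import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedhalo import (
    ChannelBand,
    SegmentationParams,
    band_mask,
    default_params,
    generate_plate,
    isodata_threshold,
    load_presets,
    segment_mucilage,
    suggest_params,
)
from seedhalo.errors import DegenerateHistogramError, ParameterError
from seedhalo.imaging import HSVPlanes, rgb_to_hsv_planes
from seedhalo.synthetic import PlateSpec


def _planes(h, s, v):
    def plane(x):
        return np.full((2, 2), x, dtype=np.uint8)

    return HSVPlanes(plane(h), plane(s), plane(v))


def brute_force_intermeans(hist):
    """Exhaustive 256-candidate fixed-point search: every T that reproduces
    itself under T = round((mean<=T + mean>T)/2), ties rounding half up."""
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(256.0)
    fixed = []
    for t in range(256):
        lo, hi = hist[: t + 1], hist[t + 1 :]
        if lo.sum() == 0 or hi.sum() == 0:
            continue
        m1 = (levels[: t + 1] * lo).sum() / lo.sum()
        m2 = (levels[t + 1 :] * hi).sum() / hi.sum()
        if t == math.floor((m1 + m2) / 2.0 + 0.5):
            fixed.append(t)
    return fixed


class TestDefaults:
    def test_mucilage_band_anchors(self):
        p = default_params("mucilage")
        assert p.h_band == (172, 255)
        assert p.s_band == (24, 255)
        assert p.v_band == (85, 255)

    def test_seed_band_anchors(self):
        p = default_params("seed")
        assert p.h_band == (0, 255)
        assert p.s_band == (0, 255)
        assert p.v_band == (0, 70)

    def test_unknown_target(self):
        with pytest.raises(ParameterError):
            default_params("root")


class TestBandMask:
    @pytest.mark.parametrize(
        "hsv, target, expected",
        [
            ((200, 100, 150), "mucilage", True),
            ((100, 100, 150), "mucilage", False),  # hue below band
            ((37, 5, 40), "seed", True),  # only V <= 70 binds
            ((37, 5, 90), "seed", False),
        ],
    )
    def test_membership(self, hsv, target, expected):
        mask = band_mask(_planes(*hsv), default_params(target))
        assert bool(mask.all()) is expected

    def test_pass_all_band_marks_everything(self):
        rng = np.random.default_rng(3)
        planes = HSVPlanes(*(rng.integers(0, 256, (8, 8)).astype(np.uint8) for _ in range(3)))
        full = ChannelBand(0, 255)
        params = SegmentationParams(full, full, full, target="mucilage")
        assert band_mask(planes, params).all()

    @settings(deadline=None, max_examples=40)
    @given(
        lo=st.integers(0, 255), hi=st.integers(0, 255),
        widen_lo=st.integers(0, 50), widen_hi=st.integers(0, 50),
        data_seed=st.integers(0, 2**16),
    )
    def test_widening_a_band_is_monotone(self, lo, hi, widen_lo, widen_hi, data_seed):
        if lo > hi:
            lo, hi = hi, lo
        rng = np.random.default_rng(data_seed)
        planes = HSVPlanes(*(rng.integers(0, 256, (6, 6)).astype(np.uint8) for _ in range(3)))
        full = ChannelBand(0, 255)
        narrow = SegmentationParams(ChannelBand(lo, hi), full, full, target="mucilage")
        wide = SegmentationParams(
            ChannelBand(max(0, lo - widen_lo), min(255, hi + widen_hi)), full, full, target="mucilage"
        )
        assert not (band_mask(planes, narrow) & ~band_mask(planes, wide)).any()


class TestIsodata:
    def test_two_delta_masses(self):
        hist = np.zeros(256)
        hist[50] = hist[200] = 100
        assert isodata_threshold(hist) == 125

    def test_three_mass_example(self):
        # frozen from the exhaustive intermeans fixed-point oracle
        hist = np.zeros(256)
        hist[10], hist[20], hist[240] = 100, 50, 150
        t = isodata_threshold(hist)
        assert t == 127
        assert t in brute_force_intermeans(hist)

    def test_degenerate_histograms(self):
        with pytest.raises(DegenerateHistogramError):
            isodata_threshold(np.zeros(256))
        single = np.zeros(256)
        single[42] = 10
        with pytest.raises(DegenerateHistogramError):
            isodata_threshold(single)

    def test_oracle_equivalence_on_random_histograms(self):
        """The iterative recursion lands on an exhaustive-search fixed point
        for 100 random sparse histograms."""
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 100:
            hist = rng.integers(0, 100, 256) * (rng.random(256) < 0.05)
            if np.count_nonzero(hist) < 2:
                continue
            assert isodata_threshold(hist) in brute_force_intermeans(hist)
            checked += 1


class TestSuggestParams:
    def test_bimodal_value_channel(self):
        rng = np.random.default_rng(5)
        v = np.where(rng.random((50, 50)) < 0.5, 120, 230).astype(np.uint8)
        planes = HSVPlanes(v.copy(), v.copy(), v)
        params = suggest_params(planes, "mucilage")
        assert 120 < params.v_band.low < 230

    def test_uniform_image_falls_back_to_defaults(self):
        planes = _planes(100, 100, 100)
        with pytest.warns(UserWarning, match="degenerate"):
            params = suggest_params(planes, "mucilage")
        assert params == default_params("mucilage")

    def test_suggested_bands_agree_with_defaults_on_generator_plate(self):
        """On a default-palette plate the suggested bands classify >=99% of
        true halo pixels identically to the shipped defaults."""
        spec = PlateSpec(n_seeds=6, rng_seed=21)
        image, truth = generate_plate(spec)
        planes = rgb_to_hsv_planes(image)
        suggested = suggest_params(planes, "mucilage")
        m_default = band_mask(planes, default_params("mucilage"))
        m_suggested = band_mask(planes, suggested)
        # ground-truth halo disks
        yy, xx = np.mgrid[: image.shape[0], : image.shape[1]]
        halo = np.zeros(image.shape[:2], bool)
        for _, row in truth.objects.iterrows():
            r_px = row.halo_radius_mm * spec.pixels_per_mm
            halo |= (yy - row.center_row_px) ** 2 + (xx - row.center_col_px) ** 2 <= r_px**2
        agree = (m_default == m_suggested)[halo].mean()
        assert agree >= 0.99


class TestSegmentMucilage:
    def test_annulus_is_filled_to_the_outer_contour(self):
        # purple ring with a dark "seed" disk in the middle on gel background
        img = np.zeros((101, 101, 3), dtype=np.uint8)
        img[:] = (190, 215, 235)
        yy, xx = np.mgrid[:101, :101] - 50
        d2 = yy * yy + xx * xx
        ring = (d2 <= 40**2) & (d2 > 15**2)
        seed = d2 <= 10**2
        img[ring] = (200, 120, 180)
        img[seed] = (60, 40, 30)
        mask = segment_mucilage(img)
        disk = d2 <= 40**2
        assert np.array_equal(mask, disk)

    def test_no_pixels_in_band_gives_empty_mask(self):
        img = np.full((10, 10, 3), 255, dtype=np.uint8)  # white: s=0 -> below s band
        assert not segment_mucilage(img).any()

    def test_filled_halo_contains_ring_plus_seed(self, clean_plate):
        spec, image, truth = clean_plate
        mask = segment_mucilage(image)
        ppmm = spec.pixels_per_mm
        for _, row in truth.objects.iterrows():
            r_px = row.halo_radius_mm * ppmm
            y0, x0 = int(row.center_row_px), int(row.center_col_px)
            yy, xx = np.mgrid[y0 - 3 : y0 + 4, x0 - 3 : x0 + 4]
            assert mask[yy, xx].all()  # seed interior included
            ring_px = np.pi * r_px**2 - np.pi * (row.seed_semi_major_mm * ppmm) ** 2
            assert mask.sum() >= ring_px

    def test_mask_has_no_holes(self, clean_plate):
        from scipy import ndimage

        _, image, _ = clean_plate
        mask = segment_mucilage(image)
        assert np.array_equal(mask, ndimage.binary_fill_holes(mask))

    def test_jaccard_against_ground_truth_disks(self, clean_plate):
        spec, image, truth = clean_plate
        mask = segment_mucilage(image)
        yy, xx = np.mgrid[: image.shape[0], : image.shape[1]]
        gt = np.zeros(image.shape[:2], bool)
        for _, row in truth.objects.iterrows():
            r_px = row.halo_radius_mm * spec.pixels_per_mm
            gt |= (yy - row.center_row_px) ** 2 + (xx - row.center_col_px) ** 2 <= r_px**2
        jaccard = (mask & gt).sum() / (mask | gt).sum()
        assert jaccard >= 0.98


class TestSegmentSeeds:
    def test_every_true_seed_centroid_inside_mask(self, clean_plate):
        from seedhalo import segment_seeds

        _, image, truth = clean_plate
        mask = segment_seeds(image)
        for _, row in truth.objects.iterrows():
            assert mask[int(row.center_row_px), int(row.center_col_px)]

    def test_all_background_image_is_empty(self):
        from seedhalo import segment_seeds

        img = np.full((20, 20, 3), (190, 215, 235), dtype=np.uint8)
        assert not segment_seeds(img).any()

    def test_specular_highlight_hole_filled(self):
        from seedhalo import segment_seeds

        img = np.full((30, 30, 3), (190, 215, 235), dtype=np.uint8)
        img[10:20, 10:20] = (60, 40, 30)
        img[14:16, 14:16] = (250, 250, 250)  # bright glint inside the seed
        mask = segment_seeds(img)
        assert mask[14:16, 14:16].all()


def test_presets_cover_five_species():
    presets = load_presets()
    assert set(presets) == {"linum", "arabidopsis", "camelina", "plantago", "capsella"}
    linum = presets["linum"]
    assert linum["mucilage"] == default_params("mucilage")
    assert linum["seed"] == default_params("seed")
    assert linum["mucilage_area_mm2"] == (18.0, 315.0)
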