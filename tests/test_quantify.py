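"""Unit and property tests for the threshold-gated ratio statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import starchshg as s
from conftest import shg_image, tpf_image


def naive_tpf_count(pixels, threshold):
    n = 0
    for row in pixels:
        for v in row:
            if v > threshold:
                n += 1
    return n


def naive_shg_sum(pixels, background):
    total = 0
    for row in pixels:
        for v in row:
            if v > background:
                total += v
    return total


class TestThresholdStatistics:
    @pytest.mark.parametrize(
        "pixels,threshold,expected",
        [
            (np.zeros((4, 4)), 50, 0),
            ([[50, 51], [100, 0]], 50, 2),  # 50 is not "above" 50
        ],
    )
    def test_tpf_pixel_count_examples(self, pixels, threshold, expected):
        assert s.tpf_pixel_count(tpf_image(pixels), threshold) == expected

    def test_nothing_exceeds_its_own_maximum(self):
        rng = np.random.default_rng(0)
        img = tpf_image(rng.integers(0, 300, size=(9, 9)))
        assert s.tpf_pixel_count(img, threshold=int(img.pixels.max())) == 0

    @pytest.mark.parametrize(
        "pixels,background,expected",
        [
            (np.zeros((3, 3)), 2, 0),
            ([[0, 2, 3], [5, 0, 1], [2, 2, 4]], 2, 12),  # 3 + 5 + 4
        ],
    )
    def test_shg_intensity_examples(self, pixels, background, expected):
        assert s.shg_intensity(shg_image(pixels), background) == expected

    def test_uniform_image_closed_form(self):
        bg = 2
        img = shg_image(np.full((6, 7), bg + 1))
        assert s.shg_intensity(img, bg) == 6 * 7 * (bg + 1)

    def test_matches_naive_enumeration_on_random_rasters(self):
        """Vectorized statistics equal pixel-by-pixel enumeration, exactly."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            shape = tuple(rng.integers(1, 17, size=2))
            pixels = rng.integers(0, 301, size=shape)
            thr = int(rng.integers(0, 300))
            bg = int(rng.integers(0, 10))
            assert s.tpf_pixel_count(tpf_image(pixels), thr) == naive_tpf_count(
                pixels, thr
            )
            assert s.shg_intensity(shg_image(pixels), bg) == naive_shg_sum(pixels, bg)

    def test_threshold_boundary_is_strict(self):
        """A pixel exactly at the threshold/background value is excluded."""
        img_t = tpf_image([[50, 50], [50, 50]])
        assert s.tpf_pixel_count(img_t, 50) == 0
        assert s.tpf_pixel_count(img_t, 49) == 4
        img_s = shg_image([[2, 2], [2, 3]])
        assert s.shg_intensity(img_s, 2) == 3
        # the convention is flippable in one place
        assert int(s.quantify.above(img_t.pixels, 50, strict=False).sum()) == 4

    def test_wrong_channel_rejected(self):
        with pytest.raises(s.ChannelMismatchError):
            s.tpf_pixel_count(shg_image(np.zeros((2, 2))))
        with pytest.raises(s.ChannelMismatchError):
            s.shg_intensity(tpf_image(np.zeros((2, 2))))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pixels=hnp.arrays(np.int64, (6, 6), elements=st.integers(0, 300)),
        idx=st.tuples(st.integers(0, 5), st.integers(0, 5)),
        bump=st.integers(1, 100),
        thr=st.integers(0, 120),
    )
    def test_monotonicity(self, pixels, idx, bump, thr):
        """Raising one SHG pixel never lowers I_SHG; raising the TPF
        threshold never raises Cnt_TPF."""
        base = s.shg_intensity(shg_image(pixels), 2)
        raised = pixels.copy()
        raised[idx] += bump
        assert s.shg_intensity(shg_image(raised), 2) >= base
        c_lo = s.tpf_pixel_count(tpf_image(pixels), thr)
        c_hi = s.tpf_pixel_count(tpf_image(pixels), thr + 1)
        assert c_hi <= c_lo


class TestStarchRatio:
    def test_zero_shg_gives_zero_ratio(self):
        tpf = tpf_image(np.full((5, 5), 100))
        shg = shg_image(np.zeros((5, 5)))
        q = s.starch_ratio(tpf, shg)
        assert q.ratio == 0.0 and q.valid

    def test_ratio_is_division_of_operands(self):
        tpf = tpf_image([[60, 60, 0], [60, 60, 0], [0, 0, 0]])  # Cnt = 4
        shg = shg_image([[3, 4, 0], [5, 0, 0], [0, 0, 0]])  # I = 12
        q = s.starch_ratio(tpf, shg)
        assert (q.i_shg, q.cnt_tpf, q.ratio) == (12, 4, 3.0)

    def test_scaling_retained_shg_pixels_scales_ratio(self):
        rng = np.random.default_rng(3)
        tpf = tpf_image(rng.integers(0, 200, (8, 8)))
        shg_px = rng.integers(3, 40, (8, 8))  # all already above background
        k = 5
        q1 = s.starch_ratio(tpf, shg_image(shg_px))
        qk = s.starch_ratio(tpf, shg_image(shg_px * k))
        assert qk.ratio == pytest.approx(k * q1.ratio)

    def test_zero_padding_leaves_ratio_unchanged(self):
        rng = np.random.default_rng(4)
        tpf_px = rng.integers(0, 200, (8, 8))
        shg_px = rng.integers(0, 30, (8, 8))
        q1 = s.starch_ratio(tpf_image(tpf_px), shg_image(shg_px))
        q2 = s.starch_ratio(
            tpf_image(np.pad(tpf_px, 6)), shg_image(np.pad(shg_px, 6))
        )
        assert q2.ratio == q1.ratio
        assert (q2.i_shg, q2.cnt_tpf) == (q1.i_shg, q1.cnt_tpf)

    def test_no_tpf_pixels_is_flagged_not_zero(self):
        q = s.starch_ratio(
            tpf_image(np.zeros((4, 4))), shg_image(np.full((4, 4), 9))
        )
        assert not q.valid
        assert np.isnan(q.ratio)
        assert q.i_shg > 0  # the operand is still reported

    def test_threshold_rescales_with_dwell(self):
        # 60 counts clears threshold 50 at the reference dwell, but not at
        # double the dwell where the effective threshold is 100
        px = np.full((3, 3), 60)
        assert s.tpf_pixel_count(tpf_image(px, dwell_ms=0.016), 50) == 9
        assert s.tpf_pixel_count(tpf_image(px, dwell_ms=0.032), 50) == 0
        assert (
            s.tpf_pixel_count(tpf_image(px, dwell_ms=0.032), 50, rescale_with_dwell=False)
            == 9
        )


class TestChloroplastMask:
    def test_empty_image_gives_empty_mask(self):
        assert not s.chloroplast_mask(tpf_image(np.zeros((8, 8)))).any()

    def test_zero_radius_is_raw_threshold_mask(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 120, (12, 12))
        mask = s.chloroplast_mask(tpf_image(px), 50, closing_radius_px=0)
        assert np.array_equal(mask, px > 50)

    def test_closing_fills_ring_interior(self):
        """A bright ring of radius 3 closes to a filled disk with radius-3
        closing, matching the reference morphology result."""
        from skimage.draw import circle_perimeter
        from skimage.morphology import closing, disk

        px = np.zeros((15, 15), dtype=np.int64)
        rr, cc = circle_perimeter(7, 7, 3)
        px[rr, cc] = 100
        mask = s.chloroplast_mask(tpf_image(px), 50, closing_radius_px=3)
        assert mask[7, 7]  # interior filled
        raw = px > 50
        assert np.array_equal(mask, closing(np.pad(raw, 4), disk(3))[4:-4, 4:-4])

    def test_mask_contains_raw_threshold_mask(self):
        rng = np.random.default_rng(6)
        px = rng.integers(0, 120, (20, 20))
        mask = s.chloroplast_mask(tpf_image(px), 50, closing_radius_px=2)
        assert np.all(mask[px > 50])


class TestColocalization:
    def _tpf_left_half(self):
        px = np.zeros((10, 10), dtype=np.int64)
        px[:, :5] = 100
        return tpf_image(px)

    def test_all_inside_gives_one(self):
        shg_px = np.zeros((10, 10), dtype=np.int64)
        shg_px[2:4, 1:3] = 9
        rep = s.colocalization(self._tpf_left_half(), shg_image(shg_px))
        assert rep.inside_fraction == 1.0

    def test_all_outside_gives_zero(self):
        shg_px = np.zeros((10, 10), dtype=np.int64)
        shg_px[2:4, 8:10] = 9
        rep = s.colocalization(self._tpf_left_half(), shg_image(shg_px))
        assert rep.inside_fraction == 0.0

    def test_counting_fraction(self):
        shg_px = np.zeros((10, 10), dtype=np.int64)
        shg_px[0, :4] = 9   # 4 inside (cols 0-3 < 5)
        shg_px[1, :3] = 9   # 3 inside
        shg_px[5, 7:10] = 9  # 3 outside
        rep = s.colocalization(self._tpf_left_half(), shg_image(shg_px))
        assert rep.inside_fraction == pytest.approx(0.7)

    def test_no_shg_positive_is_flagged(self):
        rep = s.colocalization(self._tpf_left_half(), shg_image(np.zeros((10, 10))))
        assert np.isnan(rep.inside_fraction)
        assert rep.flags
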