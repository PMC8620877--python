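"""Census coding: integral images, sub-region tiling, 9-bit codes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import corticolumn as cc
from corticolumn.census import Region


class TestIntegralImage:
    def test_whole_rectangle_sum_and_mean(self):
        ii = cc.build_integral(np.array([[1, 2], [3, 4]]))
        assert cc.block_mean(ii, Region(0, 0, 2, 2)) == pytest.approx(2.5)

    def test_single_pixel_region_is_identity(self, rng):
        img = rng.integers(0, 256, (7, 9))
        ii = cc.build_integral(img)
        for _ in range(10):
            x, y = rng.integers(0, 9), rng.integers(0, 7)
            assert cc.block_mean(ii, Region(int(x), int(y), 1, 1)) == img[y, x]

    def test_means_match_per_pixel_oracle_exactly(self, rng):
        img = rng.integers(0, 256, (13, 17))
        ii = cc.build_integral(img)
        for _ in range(50):
            w = int(rng.integers(1, 18))
            h = int(rng.integers(1, 14))
            x = int(rng.integers(0, 18 - w))
            y = int(rng.integers(0, 14 - h))
            direct = img[y : y + h, x : x + w].sum() / (w * h)
            assert cc.block_mean(ii, Region(x, y, w, h)) == direct

    def test_uniform_image_mean(self):
        ii = cc.build_integral(np.full((10, 10), 42))
        assert cc.block_mean(ii, Region(2, 3, 5, 4)) == 42

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            cc.build_integral(np.zeros((0, 0)))

    def test_out_of_bounds_region_rejected(self):
        ii = cc.build_integral(np.zeros((5, 5)))
        with pytest.raises(IndexError):
            cc.block_mean(ii, Region(3, 3, 4, 4))


class TestSubregions:
    def test_exact_thirds(self):
        subs = cc.subregion_bounds(Region(0, 0, 9, 9))
        assert all(s.w == 3 and s.h == 3 for s in subs)

    def test_rounding_rule_for_width_ten(self):
        subs = cc.subregion_bounds(Region(0, 0, 10, 9))
        assert [subs[i].w for i in range(3)] == [3, 4, 3]
        assert sum(subs[i].w for i in range(3)) == 10

    def test_minimal_region_gives_unit_cells(self):
        subs = cc.subregion_bounds(Region(0, 0, 3, 3))
        assert all(s.w == 1 and s.h == 1 for s in subs)

    def test_too_small_region_rejected(self):
        with pytest.raises(ValueError):
            cc.subregion_bounds(Region(0, 0, 2, 5))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(w=st.integers(3, 40), h=st.integers(3, 40))
    def test_nine_subregions_tile_exactly(self, w, h):
        """The nine sub-regions partition the region disjointly."""
        region = Region(0, 0, w, h)
        subs = cc.subregion_bounds(region)
        assert len(subs) == 9
        assert sum(s.area for s in subs) == w * h
        cover = np.zeros((h, w), dtype=int)
        for s in subs:
            cover[s.y0 : s.y0 + s.h, s.x0 : s.x0 + s.w] += 1
        assert (cover == 1).all()


class TestEncode:
    def test_uniform_image_all_ties_give_all_ones(self):
        ii = cc.build_integral(np.full((30, 30), 7))
        assert cc.encode(ii, Region(0, 0, 30, 30)) == 511

    def test_bright_left_column_sets_left_bits(self):
        img = np.full((30, 30), 30)
        img[:, :10] = 90
        ii = cc.build_integral(img)
        assert cc.encode(ii, Region(0, 0, 30, 30)) == 2**0 + 2**3 + 2**6

    def test_block_image_of_every_pattern_reproduces_its_code(self):
        """decode/encode round-trips except the unrealizable all-zero code.

        The all-zero pattern renders as a uniform image whose sub-means all
        tie the global mean, so it encodes to 511; every other pattern is
        recovered exactly, giving 511 distinct codes in total.
        """
        got = {}
        for code in range(512):
            img = cc.pattern_image(cc.decode(code))
            got[code] = cc.encode(cc.build_integral(img), Region(0, 0, 30, 30))
        assert got[0] == 511
        assert all(got[c] == c for c in range(1, 512))
        assert len(set(got.values())) == 511

    def test_code_zero_is_unrealizable(self, rng):
        """Sub-means average to the global mean, so some bit is always set."""
        for _ in range(200):
            img = rng.integers(0, 256, (12, 15))
            ii = cc.build_integral(img)
            assert cc.encode(ii, Region(0, 0, 15, 12)) != 0

    def test_affine_brightness_invariance(self, rng):
        """Codes survive gain/offset when no sub-mean ties the global mean."""
        checked = 0
        while checked < 100:
            img = rng.uniform(1, 200, (20, 20))
            region = Region(0, 0, 20, 20)
            ii = cc.build_integral(img)
            total = cc.block_mean(ii, region)
            if any(
                abs(cc.block_mean(ii, s) - total) < 1e-9
                for s in cc.subregion_bounds(region)
            ):
                continue
            gain = float(rng.uniform(0.1, 5.0))
            offset = float(rng.uniform(0.0, 100.0))
            ii2 = cc.build_integral(gain * img + offset)
            assert cc.encode(ii2, region) == cc.encode(ii, region)
            checked += 1


class TestDecode:
    @pytest.mark.parametrize(
        "code,pattern",
        [
            (511, np.ones((3, 3))),
            (0, np.zeros((3, 3))),
            (73, np.array([[1, 0, 0], [1, 0, 0], [1, 0, 0]])),
        ],
    )
    def test_known_patterns(self, code, pattern):
        assert (cc.decode(code) == pattern).all()

    @pytest.mark.parametrize("bad", [-1, 512, 1000])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            cc.decode(bad)


class TestCodeMap:
    def test_region_equal_to_aperture_gives_single_cell(self, rng):
        img = rng.integers(0, 256, (9, 9))
        cm = cc.code_map(cc.build_integral(img), Region(0, 0, 9, 9), (9, 9), 1)
        assert cm.codes.shape == (1, 1)

    def test_grid_counting(self, rng):
        img = rng.integers(0, 256, (12, 12))
        cm = cc.code_map(cc.build_integral(img), Region(0, 0, 12, 12), (9, 9), 3)
        assert cm.codes.shape == (2, 2)

    def test_cells_match_independent_encode(self, rng):
        img = rng.integers(0, 256, (20, 24))
        ii = cc.build_integral(img)
        cm = cc.code_map(ii, Region(2, 1, 20, 17), (6, 5), 2)
        for i in range(cm.codes.shape[0]):
            for j in range(cm.codes.shape[1]):
                r = Region(cm.x0 + j * cm.stride, cm.y0 + i * cm.stride, 6, 5)
                assert cm.codes[i, j] == cc.encode(ii, r)

    def test_bad_stride_rejected(self, rng):
        ii = cc.build_integral(np.zeros((9, 9), dtype=int))
        with pytest.raises(ValueError):
            cc.code_map(ii, Region(0, 0, 9, 9), (3, 3), 0)

    def test_csv_export(self, rng, tmp_path):
        img = rng.integers(0, 256, (12, 12))
        cm = cc.code_map(cc.build_integral(img), Region(0, 0, 12, 12), (9, 9), 3)
        path = tmp_path / "map.csv"
        cm.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "x,y,code" and len(lines) == 5


class TestGreyConversion:
    def test_rgb_uses_rec601_luma(self):
        rgb = np.zeros((2, 2, 3))
        rgb[..., 0] = 100  # pure red
        assert (cc.to_grey(rgb) == round(0.299 * 100)).all()

    def test_negative_brightness_rejected(self):
        with pytest.raises(ValueError):
            cc.to_grey(np.array([[-1.0, 0.0]]))
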