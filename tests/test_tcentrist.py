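"""tCENTRIST tests against independently written brute-force oracles."""

import numpy as np
import pytest

import eegspect as es
from eegspect.tcentrist import LTPConfig, NEIGHBOR_OFFSETS


# --- independent brute-force reference (kept deliberately naive) ---------

def ltp_maps_bruteforce(image, t):
    img = np.asarray(image, dtype=int)
    h, w = img.shape
    upper = np.zeros((h - 2, w - 2), dtype=int)
    lower = np.zeros((h - 2, w - 2), dtype=int)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            p = img[r, c]
            u = l = 0
            for bit, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                n = img[r + dr, c + dc]
                if n >= p + t:
                    u += 2**bit
                if n <= p - t:
                    l += 2**bit
            upper[r - 1, c - 1] = u
            lower[r - 1, c - 1] = l
    return upper, lower


def tcentrist_bruteforce(image, t, levels=(0, 1, 2)):
    upper, lower = ltp_maps_bruteforce(image, t)
    rows, cols = upper.shape
    feats = []
    for level in sorted(levels):
        g = 2**level
        rstep, cstep = rows // g, cols // g
        for i in range(g):
            r0, r1 = i * rstep, rows if i == g - 1 else (i + 1) * rstep
            for j in range(g):
                c0, c1 = j * cstep, cols if j == g - 1 else (j + 1) * cstep
                for codes in (upper, lower):
                    hist = np.zeros(256)
                    for v in codes[r0:r1, c0:c1].ravel():
                        hist[v] += 1
                    total = hist.sum()
                    feats.append(hist / total if total else hist)
    return np.concatenate(feats)


def lbp_census_bruteforce(image):
    """Plain census transform: bit set iff neighbor >= center."""
    img = np.asarray(image, dtype=int)
    h, w = img.shape
    out = np.zeros((h - 2, w - 2), dtype=int)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            v = 0
            for bit, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                if img[r + dr, c + dc] >= img[r, c]:
                    v += 2**bit
            out[r - 1, c - 1] = v
    return out


# --- LTP maps ------------------------------------------------------------

class TestLTPMaps:
    def test_constant_image_all_zero(self):
        maps = es.compute_ltp_maps(np.full((8, 8), 100), LTPConfig(threshold=5))
        assert not maps.upper_codes.any() and not maps.lower_codes.any()

    def test_bright_center_hand_enumeration(self):
        img = np.zeros((3, 3), dtype=np.uint8)
        img[1, 1] = 100
        maps = es.compute_ltp_maps(img, LTPConfig(threshold=5))
        assert maps.upper_codes[0, 0] == 0
        assert maps.lower_codes[0, 0] == 255

    def test_shift_invariance(self, rng):
        img = rng.integers(0, 200, size=(16, 16))
        cfg = LTPConfig(threshold=5)
        a = es.compute_ltp_maps(img, cfg)
        b = es.compute_ltp_maps(img + 10, cfg)
        np.testing.assert_array_equal(a.upper_codes, b.upper_codes)
        np.testing.assert_array_equal(a.lower_codes, b.lower_codes)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            es.compute_ltp_maps(np.zeros((2, 5)))

    def test_threshold_zero_degenerates_to_census_transform(self, rng):
        """t = 0: the upper map is the LBP '>=' census code; the lower map is
        its strict-inequality complement."""
        img = rng.integers(0, 256, size=(12, 12))
        maps = es.compute_ltp_maps(img, LTPConfig(threshold=0))
        census = lbp_census_bruteforce(img)
        np.testing.assert_array_equal(maps.upper_codes, census)
        # lower bit set iff neighbor <= center, i.e. (not >) == (>= reversed)
        h, w = img.shape
        for r in range(1, h - 1):
            for c in range(1, w - 1):
                for bit, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                    expect = img[r + dr, c + dc] <= img[r, c]
                    got = bool(maps.lower_codes[r - 1, c - 1] & (1 << bit))
                    assert got == expect


# --- pyramid geometry ----------------------------------------------------

class TestPyramidBlocks:
    def test_default_layout_on_126(self):
        blocks = es.pyramid_blocks((126, 126), (0, 1, 2))
        assert len(blocks) == 21
        level2 = blocks[5:]
        widths = {b[3] - b[2] for b in level2}
        heights = {b[1] - b[0] for b in level2}
        assert widths == {31, 33} and heights == {31, 33}

    def test_single_level_is_full_map(self):
        assert es.pyramid_blocks((10, 7), (0,)) == [(0, 10, 0, 7)]

    @pytest.mark.parametrize("shape", [(126, 126), (30, 50), (9, 9)])
    def test_each_level_tiles_exactly_once(self, shape):
        for level in (0, 1, 2):
            cover = np.zeros(shape, dtype=int)
            for (r0, r1, c0, c1) in es.pyramid_blocks(shape, (level,)):
                cover[r0:r1, c0:c1] += 1
            np.testing.assert_array_equal(cover, 1)


# --- histograms and the full descriptor ----------------------------------

class TestFeatures:
    def test_constant_image_mass_in_bin_zero(self):
        fv = es.extract_tcentrist(np.full((32, 32), 7), LTPConfig())
        values = fv.values.reshape(-1, 256)
        np.testing.assert_allclose(values[:, 0], 1.0)
        np.testing.assert_allclose(values[:, 1:], 0.0)

    def test_histogram_mass_conservation(self, rng):
        img = rng.integers(0, 256, size=(40, 40))
        maps = es.compute_ltp_maps(img)
        blocks = es.pyramid_blocks(maps.upper_codes.shape, (0, 1))
        fv = es.block_histograms(maps, blocks)
        sums = fv.values.reshape(-1, 256).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_feature_length_formula(self):
        assert LTPConfig(pyramid_levels=(0, 1, 2)).feature_length == 10752
        assert LTPConfig(pyramid_levels=(0,)).feature_length == 512
        fv = es.extract_tcentrist(np.zeros((128, 128), dtype=np.uint8))
        assert fv.values.shape == (10752,)

    def test_determinism(self, rng):
        img = rng.integers(0, 256, size=(64, 64))
        a = es.extract_tcentrist(img).values
        b = es.extract_tcentrist(img.copy()).values
        np.testing.assert_array_equal(a, b)

    def test_global_shift_leaves_descriptor_unchanged(self, rng):
        img = rng.integers(0, 200, size=(32, 32))
        a = es.extract_tcentrist(img).values
        b = es.extract_tcentrist(img + 30).values
        np.testing.assert_array_equal(a, b)

    def test_out_of_bounds_block_rejected(self, rng):
        maps = es.compute_ltp_maps(rng.integers(0, 256, size=(10, 10)))
        with pytest.raises(ValueError, match="out of bounds"):
            es.block_histograms(maps, [(0, 99, 0, 2)])

    def test_matches_bruteforce_oracle(self, rng):
        """Exact equivalence with the naive reference on random images of
        mixed sizes and all spec thresholds."""
        for i in range(50):
            side_r = int(rng.integers(8, 65))
            side_c = int(rng.integers(8, 65))
            img = rng.integers(0, 256, size=(side_r, side_c))
            t = [0, 2, 5, 10][i % 4]
            got = es.extract_tcentrist(img, LTPConfig(threshold=t)).values
            want = tcentrist_bruteforce(img, t)
            np.testing.assert_array_equal(got, want)
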