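"""Tests for GLCM descriptors, colour conversion and entropy maps."""

import numpy as np
import pytest

from hqcolony.exceptions import InvalidParameterError
from hqcolony.features import (
    FEATURE_SETS,
    entropy_map,
    feature_map_stack,
    glcm,
    haralick_descriptors,
    luminance,
    rebin_gray,
    rgb_to_luv,
    sliding_feature_maps,
)

from oracles import brute_glcm_descriptors


class TestRebinGray:
    def test_identity_for_full_range_8bit(self, rng):
        img = rng.integers(0, 256, size=(20, 20))
        img.flat[0], img.flat[1] = 0, 255  # span the full range
        out = rebin_gray(img, L=256)
        assert np.array_equal(out.values, img)

    def test_two_level_rebin(self):
        out = rebin_gray(np.array([[0, 255], [255, 0]]), L=2)
        assert np.array_equal(out.values, [[0, 1], [1, 0]])

    def test_constant_image_single_bin(self):
        out = rebin_gray(np.full((4, 4), 7.0), L=256)
        assert np.all(out.values == 0)

    def test_invalid_levels(self):
        with pytest.raises(InvalidParameterError):
            rebin_gray(np.zeros((2, 2)), L=1)


class TestGLCM:
    def test_worked_2x2_example(self):
        # [[0,1],[0,1]] with offset (0,1): both horizontal pairs are (0,1)
        g = glcm(np.array([[0, 1], [0, 1]]), offset=(0, 1), L=2)
        assert g.counts[0, 1] == 2
        assert g.counts.sum() == 2
        assert g.normalized[0, 1] == 1.0

    def test_constant_window_diagonal(self):
        g = glcm(np.full((3, 3), 2), offset=(0, 1), L=4)
        assert g.normalized[2, 2] == 1.0

    def test_normalization_sums_to_one(self, rng):
        g = glcm(rng.integers(0, 8, size=(5, 5)), offset=(1, 1), L=8)
        assert np.isclose(g.normalized.sum(), 1.0, atol=1e-12)

    def test_zero_offset_rejected(self):
        with pytest.raises(InvalidParameterError):
            glcm(np.zeros((3, 3), dtype=int), offset=(0, 0))


class TestHaralick:
    def test_constant_window(self):
        g = glcm(np.full((3, 3), 1), offset=(0, 1), L=4)
        with pytest.warns(UserWarning, match="correlation"):
            contrast, correlation, energy, homogeneity = haralick_descriptors(g)
        assert contrast == 0.0
        assert energy == 1.0
        assert homogeneity == 1.0
        assert correlation == 0.0

    def test_single_offdiagonal_cell(self):
        # p(0,1) = 1: contrast 1, energy 1, homogeneity 1/2
        g = glcm(np.array([[0, 1], [0, 1]]), offset=(0, 1), L=2)
        with pytest.warns(UserWarning):
            contrast, _, energy, homogeneity = haralick_descriptors(g)
        assert contrast == 1.0
        assert energy == 1.0
        assert homogeneity == 0.5

    def test_descriptor_bounds(self, rng):
        for _ in range(50):
            g = glcm(rng.integers(0, 8, size=(5, 5)), offset=(0, 1), L=8)
            contrast, correlation, energy, homogeneity = haralick_descriptors(g)
            assert 0.0 <= contrast <= 49.0
            assert 0.0 < energy <= 1.0
            assert 0.0 < homogeneity <= 1.0
            assert -1.0 - 1e-12 <= correlation <= 1.0 + 1e-12

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            window = rng.integers(0, 6, size=(5, 5))
            g = glcm(window, offset=(0, 1), L=6)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                ours = haralick_descriptors(g)
            oracle = brute_glcm_descriptors(window, offset=(0, 1))
            assert np.allclose(ours, oracle, atol=1e-12)

    def test_matches_skimage_reference(self, rng):
        # independent cross-check against the reference co-occurrence
        # implementation (non-symmetric, single offset)
        from skimage.feature import graycomatrix, graycoprops

        for _ in range(25):
            window = rng.integers(0, 8, size=(5, 5)).astype(np.uint8)
            if window[:, :-1].std() == 0 or window[:, 1:].std() == 0:
                continue
            g = glcm(window, offset=(0, 1), L=8)
            ref = graycomatrix(window, [1], [0], levels=8, symmetric=False, normed=True)
            contrast, correlation, energy, homogeneity = haralick_descriptors(g)
            assert np.isclose(contrast, graycoprops(ref, "contrast")[0, 0], atol=1e-10)
            assert np.isclose(correlation, graycoprops(ref, "correlation")[0, 0], atol=1e-10)
            assert np.isclose(energy, graycoprops(ref, "ASM")[0, 0], atol=1e-10)
            # skimage's "homogeneity" squares the level difference; apply the
            # |i-j| kernel to skimage's matrix to check ours
            i, j = np.indices((8, 8))
            hom_ref = float(np.sum(ref[:, :, 0, 0] / (1.0 + np.abs(i - j))))
            assert np.isclose(homogeneity, hom_ref, atol=1e-10)


class TestSlidingMaps:
    def test_constant_image(self):
        gray = rebin_gray(np.full((10, 10), 5.0), L=8)
        with pytest.warns(UserWarning):
            maps = sliding_feature_maps(gray, window=5)
        assert np.all(maps["contrast"] == 0.0)
        assert np.all(maps["homogeneity"] == 1.0)
        assert np.all(maps["energy"] == 1.0)

    def test_step_edge_band(self):
        img = np.zeros((11, 12), dtype=int)
        img[:, 6:] = 7
        gray = rebin_gray(img, L=8, value_range=(0, 7))
        with pytest.warns(UserWarning):
            maps = sliding_feature_maps(gray, window=5, offset=(0, 1))
        # contrast nonzero only where the window straddles the edge
        nonzero_cols = np.unique(np.nonzero(maps["contrast"])[1])
        assert nonzero_cols.min() >= 6 - 3 and nonzero_cols.max() <= 6 + 2
        assert maps["contrast"][5, 0] == 0.0
        assert maps["contrast"][5, 6] > 0.0

    def test_output_shape_matches_input(self, rng):
        gray = rebin_gray(rng.integers(0, 256, size=(17, 23)), L=256)
        maps = sliding_feature_maps(gray, window=5)
        for m in maps.values():
            assert m.shape == (17, 23)

    def test_even_window_rejected(self, rng):
        gray = rebin_gray(rng.integers(0, 8, size=(6, 6)), L=8)
        with pytest.raises(InvalidParameterError):
            sliding_feature_maps(gray, window=4)

    def test_matches_per_window_computation(self, rng):
        """Every map pixel equals the single-window GLCM descriptors of the
        replicate-padded neighbourhood."""
        import warnings as _w

        img = rng.integers(0, 6, size=(8, 9))
        gray = rebin_gray(img, L=6, value_range=(0, 5))
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            maps = sliding_feature_maps(gray, window=5, offset=(0, 1))
            padded = np.pad(gray.values, 2, mode="edge")
            for r in range(8):
                for c in range(9):
                    window = padded[r : r + 5, c : c + 5]
                    expected = brute_glcm_descriptors(window, offset=(0, 1))
                    got = (
                        maps["contrast"][r, c],
                        maps["correlation"][r, c],
                        maps["energy"][r, c],
                        maps["homogeneity"][r, c],
                    )
                    assert np.allclose(got, expected, atol=1e-10)

    def test_shift_invariance(self, rng):
        img = rng.integers(10, 100, size=(10, 10))
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            a = sliding_feature_maps(rebin_gray(img, L=32), window=5)
            b = sliding_feature_maps(rebin_gray(img + 55, L=32), window=5)
        for key in a:
            assert np.allclose(a[key], b[key], atol=1e-12)


class TestColourConversion:
    def test_white_and_black(self):
        white = np.full((1, 1, 3), 255, dtype=np.uint8)
        black = np.zeros((1, 1, 3), dtype=np.uint8)
        assert rgb_to_luv(white)[0, 0, 0] == pytest.approx(100.0, abs=0.01)
        assert np.allclose(rgb_to_luv(black)[0, 0], 0.0, atol=1e-6)

    def test_against_independent_conversion(self, rng):
        # manual sRGB -> XYZ -> L*u*v* under D65
        def reference_luv(rgb):
            c = rgb / 255.0
            c = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
            M = np.array([
                [0.412453, 0.357580, 0.180423],
                [0.212671, 0.715160, 0.072169],
                [0.019334, 0.119193, 0.950227],
            ])
            X, Y, Z = M @ c
            Xn, Yn, Zn = M @ np.ones(3)
            yr = Y / Yn
            L = 116 * yr ** (1 / 3) - 16 if yr > (6 / 29) ** 3 else (29 / 3) ** 3 * yr
            d = X + 15 * Y + 3 * Z
            dn = Xn + 15 * Yn + 3 * Zn
            up, vp = (4 * X / d, 9 * Y / d) if d > 0 else (0.0, 0.0)
            upn, vpn = 4 * Xn / dn, 9 * Yn / dn
            return np.array([L, 13 * L * (up - upn), 13 * L * (vp - vpn)])

        pixels = rng.integers(0, 256, size=(20, 1, 3)).astype(np.uint8)
        ours = rgb_to_luv(pixels)
        for k in range(20):
            assert np.allclose(ours[k, 0], reference_luv(pixels[k, 0].astype(float)), atol=0.1)

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            rgb_to_luv(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            luminance(np.zeros((4, 4, 2)))


class TestEntropyMap:
    def test_constant_image(self):
        gray = rebin_gray(np.full((8, 8), 3.0), L=8)
        assert np.all(entropy_map(gray, window=5) == 0.0)

    def test_two_levels_equal_proportion_one_bit(self):
        img = np.indices((9, 8)).sum(axis=0) % 2  # checkerboard
        gray = rebin_gray(img, L=2, value_range=(0, 1))
        ent = entropy_map(gray, window=5)
        # interior windows hold 12 or 13 of each level out of 25
        p = 13 / 25
        expected = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        assert np.allclose(ent[4, 4], expected, atol=1e-12)

    def test_uniform_window_max_entropy(self):
        # 25 distinct levels in every interior window -> log2(25) bits
        img = (np.arange(25).reshape(5, 5) * 1.0)
        img = np.tile(img, (3, 3))
        gray = rebin_gray(img, L=25, value_range=(0, 24))
        ent = entropy_map(gray, window=5)
        assert ent.max() == pytest.approx(np.log2(25), abs=1e-10)
        assert np.all(ent <= np.log2(25) + 1e-12)

    def test_matches_brute_force(self, rng):
        img = rng.integers(0, 6, size=(7, 7))
        gray = rebin_gray(img, L=6, value_range=(0, 5))
        ent = entropy_map(gray, window=3)
        padded = np.pad(gray.values, 1, mode="edge")
        for r in range(7):
            for c in range(7):
                _, counts = np.unique(padded[r : r + 3, c : c + 3], return_counts=True)
                p = counts / counts.sum()
                assert ent[r, c] == pytest.approx(-(p * np.log2(p)).sum(), abs=1e-12)


class TestFeatureStack:
    def test_stack_contents_and_alignment(self, rng):
        img = rng.integers(0, 256, size=(24, 24, 3)).astype(np.uint8)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            stack = feature_map_stack(img, window=5)
        expected = {"R", "G", "B", "L*", "u*", "v*", "contrast", "correlation",
                    "energy", "homogeneity", "entropy"}
        assert set(stack.maps) == expected
        assert all(m.shape == (24, 24) for m in stack.maps.values())
        assert set(stack.select("homogeneity")) == {"homogeneity"}
        assert list(stack.select("luv")) == ["L*", "u*", "v*"]

    def test_feature_sets_registry(self):
        assert sorted(FEATURE_SETS) == [
            "contrast", "correlation", "energy", "homogeneity", "luv", "rgb",
        ]
        assert sum(len(v) == 3 for v in FEATURE_SETS.values()) == 2
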