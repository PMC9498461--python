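import numpy as np
import pytest
from skimage.color import hsv2rgb

from teamoist.image_features import (
    FEATURE_NAMES,
    GlcmParams,
    build_glcm,
    center_roi,
    extract_all,
    extract_color_features,
    extract_texture_features,
    quantize_gray,
)


def brute_force_glcm(gray, levels, distance, angles_deg, symmetric):
    """Direct pair enumeration, independent of the library construction."""
    H, W = gray.shape
    offsets = {0: (0, distance), 45: (-distance, distance),
               90: (-distance, 0), 135: (-distance, -distance)}
    mats = []
    for ang in angles_deg:
        dr, dc = offsets[int(ang)]
        P = np.zeros((levels, levels))
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W:
                    P[gray[r, c], gray[r2, c2]] += 1
        if symmetric:
            P = P + P.T
        mats.append(P)
    P = np.mean(mats, axis=0)
    return P / P.sum()


def brute_force_texture(gray, levels):
    """Double-loop summation of every statistic from first principles."""
    flat = gray.ravel()
    p = np.array([(flat == z).sum() for z in range(levels)], float)
    p /= flat.size
    m = sum(z * p[z] for z in range(levels))
    U = sum(p[z] ** 2 for z in range(levels))
    e = -sum(p[z] * np.log2(p[z]) for z in range(levels) if p[z] > 0)
    v = sum((z - m) ** 2 * p[z] for z in range(levels))
    P = brute_force_glcm(gray, levels, 1, (0, 45, 90, 135), True)
    en = ii = idm = 0.0
    mu_i = mu_j = 0.0
    for i in range(levels):
        for j in range(levels):
            en += P[i, j] ** 2
            ii += (i - j) ** 2 * P[i, j]
            idm += P[i, j] / (1 + (i - j) ** 2)
            mu_i += i * P[i, j]
            mu_j += j * P[i, j]
    si = np.sqrt(sum((i - mu_i) ** 2 * P[i, j]
                     for i in range(levels) for j in range(levels)))
    sj = np.sqrt(sum((j - mu_j) ** 2 * P[i, j]
                     for i in range(levels) for j in range(levels)))
    c = sum((i - mu_i) * (j - mu_j) * P[i, j]
            for i in range(levels) for j in range(levels)) / (si * sj)
    return {"m": m, "U": U, "e": e, "v": v, "c": c, "i": ii, "IDM": idm, "en": en}


class TestColorFeatures:
    def test_pure_red(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[..., 0] = 255
        f = extract_color_features(img)
        assert f["R"] == 255 and f["G"] == 0 and f["B"] == 0
        assert abs(f["H"]) < 1e-9 or abs(f["H"] - 360) < 1e-9
        assert f["S"] == pytest.approx(1.0) and f["V"] == pytest.approx(1.0)

    def test_white_point_lab(self):
        img = np.full((4, 4, 3), 255, np.uint8)
        f = extract_color_features(img)
        assert abs(f["L"] - 100) < 0.5
        assert abs(f["a"]) < 0.5 and abs(f["b"]) < 0.5

    def test_hue_mean_is_circular(self):
        # hues 350 deg and 10 deg average to ~0 deg, never 180 deg
        hsv = np.array([[[350 / 360, 1.0, 1.0], [10 / 360, 1.0, 1.0]]])
        img = np.round(hsv2rgb(hsv) * 255).astype(np.uint8)
        H = extract_color_features(img)["H"]
        assert min(H, 360 - H) < 1.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            extract_color_features(np.zeros((0, 0, 3), np.uint8))


class TestGlcm:
    def test_constant_image_single_entry(self):
        P = build_glcm(np.full((6, 6), 3, np.uint8), GlcmParams(levels=8))
        assert P[3, 3] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_checkerboard_horizontal_pairs(self):
        board = np.array([[0, 1], [1, 0]], np.uint8)
        params = GlcmParams(levels=2, angles=(0.0,), symmetric=True)
        P = build_glcm(board, params)
        # two horizontal pairs, both between levels 0 and 1
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == 0 and P[1, 1] == 0

    def test_normalized_and_symmetric(self, rng):
        gray = rng.integers(0, 16, size=(12, 12)).astype(np.uint8)
        P = build_glcm(gray, GlcmParams(levels=16))
        assert np.all(P >= 0)
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T, atol=1e-12)

    def test_matches_brute_force(self, rng):
        gray = rng.integers(0, 8, size=(9, 7)).astype(np.uint8)
        P = build_glcm(gray, GlcmParams(levels=8))
        np.testing.assert_allclose(P, brute_force_glcm(gray, 8, 1,
                                                       (0, 45, 90, 135), True),
                                   atol=1e-12)

    def test_roi_smaller_than_offset_rejected(self):
        with pytest.raises(ValueError):
            build_glcm(np.zeros((1, 1), np.uint8), GlcmParams(levels=2))


class TestTextureFeatures:
    def test_constant_image_degenerate_values(self):
        gray = np.full((8, 8), 5, np.uint8)
        with pytest.warns(UserWarning, match="correlation"):
            f = extract_texture_features(gray, GlcmParams(levels=16))
        assert f["U"] == pytest.approx(1.0)
        assert f["e"] == pytest.approx(0.0)
        assert f["v"] == pytest.approx(0.0)
        assert f["en"] == pytest.approx(1.0)
        assert f["i"] == pytest.approx(0.0)
        assert f["IDM"] == pytest.approx(1.0)
        assert f["c"] == 0.0

    def test_checkerboard_histogram_entropy(self):
        board = np.indices((6, 6)).sum(axis=0) % 2
        f = extract_texture_features(board.astype(np.uint8),
                                     GlcmParams(levels=2))
        assert f["e"] == pytest.approx(1.0)  # p = (0.5, 0.5) -> 1 bit
        assert f["U"] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        gray = rng.integers(0, 8, size=(10, 10)).astype(np.uint8)
        got = extract_texture_features(gray, GlcmParams(levels=8))
        want = brute_force_texture(gray, 8)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-10), key


class TestExtractAll:
    def test_seventeen_named_features(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        f = extract_all(img, GlcmParams(levels=8))
        assert tuple(f) == FEATURE_NAMES
        assert len(f) == 17
        assert all(np.isfinite(v) for v in f.values())

    def test_deterministic(self, rng):
        img = rng.integers(0, 256, size=(12, 12, 3)).astype(np.uint8)
        assert extract_all(img) == extract_all(img.copy())

    def test_rotation_invariant_texture(self, rng):
        img = rng.integers(0, 256, size=(14, 14, 3)).astype(np.uint8)
        rot = np.rot90(img, k=1, axes=(0, 1)).copy()
        params = GlcmParams(levels=8)
        a = extract_texture_features(quantize_gray(img, 8), params)
        b = extract_texture_features(quantize_gray(rot, 8), params)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-10), key


def test_center_roi_and_size_guard(rng):
    img = rng.integers(0, 256, size=(20, 30, 3)).astype(np.uint8)
    roi = center_roi(img, 10)
    assert roi.shape == (10, 10, 3)
    with pytest.raises(ValueError):
        center_roi(img, 25)
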