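"""Texture, color and shape descriptors against independent oracles."""

import numpy as np
import pytest

import facebeauty as fb
from facebeauty.descriptors import (DEFAULT_OFFSETS, GLCMMatrix, glcm,
                                    hsv_histogram, hu_moments, quantize_gray,
                                    texture_features, to_grayscale, fuse)


def brute_force_glcm_features(gray, levels, offset):
    """Independent double-loop GLCM + Table-style statistics (test oracle)."""
    q = (gray.astype(int) * levels) // 256
    h, w = q.shape
    dy, dx = offset
    m = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w:
                m[q[r, c], q[r2, c2]] += 1
    m = m + m.T
    p = m / m.sum()
    contrast = homogeneity = energy = 0.0
    num = 0.0
    mu_i = sum(i * p[i, j] for i in range(levels) for j in range(levels))
    mu_j = sum(j * p[i, j] for i in range(levels) for j in range(levels))
    var_i = sum((i - mu_i) ** 2 * p[i, j]
                for i in range(levels) for j in range(levels))
    var_j = sum((j - mu_j) ** 2 * p[i, j]
                for i in range(levels) for j in range(levels))
    for i in range(levels):
        for j in range(levels):
            contrast += abs(i - j) ** 2 * p[i, j]
            homogeneity += p[i, j] / (1 + abs(i - j))
            energy += p[i, j] ** 2
            num += (i - mu_i) * (j - mu_j) * p[i, j]
    corr = num / np.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 \
        else float("nan")
    return contrast, homogeneity, corr, energy


class TestGrayscale:
    def test_white_and_red(self):
        white = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert (to_grayscale(white) == 255).all()
        red = np.zeros((4, 4, 3), dtype=np.uint8)
        red[..., 0] = 255
        assert (to_grayscale(red) == round(0.299 * 255)).all()

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="3-channel"):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestGLCM:
    def test_constant_image_single_cell(self):
        g = glcm(np.full((4, 4), 100, dtype=np.uint8), levels=8,
                 offsets=[(0, 1)])
        p = g.p[0]
        k = (100 * 8) // 256
        assert p[k, k] == 1.0
        assert p.sum() == pytest.approx(1.0)
        t = texture_features(g)
        assert t.contrast == 0.0
        assert t.homogeneity == 1.0
        assert t.energy == 1.0
        assert np.isnan(t.correlation)

    def test_checkerboard_hand_derivation(self):
        """2-level 4x4 checkerboard, offset (0,1): every horizontal pair is
        a (0,1) or (1,0) transition, so p has 0.5 on each off-diagonal cell
        and the statistics are (1, 0.5, -1, 0.5) by direct evaluation."""
        board = np.indices((4, 4)).sum(axis=0) % 2 * 255
        g = glcm(board.astype(np.uint8), levels=2, offsets=[(0, 1)])
        np.testing.assert_allclose(g.p[0], [[0, 0.5], [0.5, 0]])
        t = texture_features(g)
        assert (t.contrast, t.homogeneity, t.energy) == (1.0, 0.5, 0.5)
        assert t.correlation == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self, rng):
        """50 random 8x8 images, G in {4, 8}, the four standard offsets."""
        for trial in range(50):
            img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
            levels = 4 if trial % 2 else 8
            for off in DEFAULT_OFFSETS:
                ours = texture_features(
                    glcm(img, levels=levels, offsets=[off]))
                expected = brute_force_glcm_features(img, levels, off)
                got = (ours.contrast, ours.homogeneity, ours.correlation,
                       ours.energy)
                np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_counts_agree_with_skimage(self, rng):
        """Cross-check co-occurrence counting against graycomatrix."""
        from skimage.feature import graycomatrix

        img = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
        ours = glcm(img * 32, levels=8, offsets=[(0, 1)], symmetric=True,
                    normalize=False)
        ref = graycomatrix(img, distances=[1], angles=[0], levels=8,
                           symmetric=True, normed=False)
        np.testing.assert_array_equal(ours.p[0], ref[:, :, 0, 0])

    def test_multi_offset_features_average(self, rng):
        img = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
        combined = texture_features(glcm(img, offsets=DEFAULT_OFFSETS))
        singles = [texture_features(glcm(img, offsets=[o]))
                   for o in DEFAULT_OFFSETS]
        assert combined.contrast == pytest.approx(
            np.mean([s.contrast for s in singles]))

    def test_normalized_output_sums_to_one(self, rng):
        img = rng.integers(0, 256, size=(6, 9)).astype(np.uint8)
        for m in glcm(img).p:
            assert m.sum() == pytest.approx(1.0)
            assert (m >= 0).all()

    def test_offset_exceeding_image_raises(self):
        with pytest.raises(ValueError, match="offset"):
            glcm(np.zeros((2, 2), dtype=np.uint8), offsets=[(0, 5)])


def blob_image(cx=40.0, cy=30.0, r=12.0, size=96):
    """Compact anisotropic bright blob on black; non-trivial Hu moments.

    Quartic falloff keeps essentially all mass within ~2r of the centre so
    translated copies are not clipped differently at the borders; the
    second lobe's offset scales with r so resizing is a true scaling.
    """
    y, x = np.mgrid[0:size, 0:size].astype(float)
    z = np.exp(-(((x - cx) / r) ** 2 + ((y - cy) / (0.6 * r)) ** 2) ** 2)
    z += 0.5 * np.exp(-((((x - cx - 1.25 * r) / (0.5 * r)) ** 2
                         + ((y - cy + 0.67 * r) / r) ** 2) ** 2))
    return np.rint(z * 255).astype(np.uint8)


class TestHuMoments:
    def test_matches_skimage_oracle(self, rng):
        # skimage indexes moments (row, col); we use image (x=col, y=row)
        # coordinates.  The conventions differ by a transpose — a
        # reflection — so h0..h5 agree and h6 flips sign.
        from skimage.measure import (moments_central, moments_hu,
                                     moments_normalized)

        img = rng.random((20, 25))
        ref = moments_hu(moments_normalized(moments_central(img)))
        got = hu_moments(img).as_vector()
        np.testing.assert_allclose(got[:6], ref[:6], rtol=1e-9, atol=1e-15)
        assert got[6] == pytest.approx(-ref[6], rel=1e-9)

    def test_translation_invariance(self):
        a = hu_moments(blob_image(36, 30)).as_vector()
        b = hu_moments(blob_image(56, 50)).as_vector()
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-20)

    def test_rotation_invariance(self):
        img = blob_image()
        for k in (1, 2):
            rot = np.rot90(img, k)
            np.testing.assert_allclose(hu_moments(rot).as_vector()[:6],
                                       hu_moments(img).as_vector()[:6],
                                       rtol=1e-6)

    def test_scale_invariance_on_rasterized_shape(self):
        small = blob_image(40, 36, 10, 96)
        big = blob_image(80, 72, 20, 192)
        np.testing.assert_allclose(hu_moments(big).as_vector()[:2],
                                   hu_moments(small).as_vector()[:2],
                                   rtol=1e-3)

    def test_reflection_flips_seventh_sign_only(self):
        img = blob_image()
        a = hu_moments(img).as_vector()
        b = hu_moments(img[:, ::-1]).as_vector()
        np.testing.assert_allclose(a[:6], b[:6], rtol=1e-9)
        assert a[6] == pytest.approx(-b[6], rel=1e-9)
        assert a[6] != 0

    def test_verbatim_variant_differs_in_h2_h4_h5(self):
        img = blob_image()
        std = hu_moments(img, "standard").as_vector()
        verb = hu_moments(img, "verbatim").as_vector()
        same = np.isclose(std, verb, rtol=1e-12, atol=0)
        np.testing.assert_array_equal(same, [True, True, False, True,
                                             False, False, True])

    def test_zero_mass_image_rejected(self):
        with pytest.raises(ValueError, match="zero-mass"):
            hu_moments(np.zeros((5, 5)))


class TestHSVHistogram:
    def test_pure_red_masses(self):
        red = np.zeros((8, 8, 3), dtype=np.uint8)
        red[..., 0] = 255
        h = hsv_histogram(red, bins_per_channel=16)
        assert h.hue[0] == 1.0
        assert h.saturation[-1] == 1.0
        assert h.value[-1] == 1.0

    def test_channels_each_sum_to_one(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        h = hsv_histogram(img)
        for chan in (h.hue, h.saturation, h.value):
            assert chan.sum() == pytest.approx(1.0)
            assert (chan >= 0).all()

    def test_gray_image_is_unsaturated(self):
        img = np.full((8, 8, 3), 123, dtype=np.uint8)
        assert hsv_histogram(img).saturation[0] == 1.0


class TestFuse:
    def _parts(self, template):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        img[5:15, 5:15] = (200, 150, 120)
        gray = to_grayscale(img)
        return (fb.feature_set(template), texture_features(glcm(gray)),
                hsv_histogram(img), hu_moments(gray))

    def test_full_fusion_length_and_order(self, template):
        fs, t, c, s = self._parts(template)
        fused = fuse(fs, t, c, s, blocks=("T", "C", "S"))
        assert len(fused) == 19 + 4 + 48 + 7 == 78
        assert fused.names[:19] == fs.names
        assert fused.names[19].startswith("glcm_")
        assert fused.names[23].startswith("hsv_")
        assert fused.names[-7].startswith("hu_")

    def test_empty_blocks_equals_fs(self, template):
        fs, *_ = self._parts(template)
        fused = fuse(fs, blocks=())
        np.testing.assert_array_equal(fused.as_vector(), fs.as_vector())

    def test_unknown_and_missing_blocks_raise(self, template):
        fs, t, c, s = self._parts(template)
        with pytest.raises(ValueError, match="unknown"):
            fuse(fs, t, c, s, blocks=("X",))
        with pytest.raises(ValueError, match="not provided"):
            fuse(fs, texture=t, blocks=("T", "C"))

    def test_nan_correlation_mapped_to_zero_with_warning(self, template):
        fs, *_ = self._parts(template)
        t = texture_features(glcm(np.full((5, 5), 7, dtype=np.uint8)))
        assert np.isnan(t.correlation)
        with pytest.warns(UserWarning, match="correlation"):
            fused = fuse(fs, texture=t, blocks=("T",))
        assert np.isfinite(fused.as_vector()).all()
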