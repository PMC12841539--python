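"""Grayscale conversion, Otsu thresholding and binary morphology."""

import numpy as np
import pytest
from scipy import ndimage

from kernelseg import preprocess as pp


def brute_force_otsu(img: np.ndarray) -> int:
    """Independent exhaustive search over all 256 thresholds."""
    hist = np.bincount(img.ravel(), minlength=256) / img.size
    levels = np.arange(256.0)
    mu = float((levels * hist).sum())
    sigma = np.zeros(256)
    for t in range(256):
        w1 = hist[: t + 1].sum()
        w2 = 1.0 - w1
        if w1 <= 0 or w2 <= 0:
            continue
        m1 = (levels[: t + 1] * hist[: t + 1]).sum() / w1
        m2 = (levels[t + 1 :] * hist[t + 1 :]).sum() / w2
        sigma[t] = w1 * (m1 - mu) ** 2 + w2 * (m2 - mu) ** 2
    peak = sigma.max()
    return int(np.flatnonzero(sigma >= peak - 1e-9 * max(peak, 1.0)).min())


class TestGrayscale:
    def test_equal_channels_pass_through_weights(self):
        img = np.full((2, 3, 3), 100, np.uint8)
        assert (pp.to_grayscale(img) == 100).all()

    def test_pure_red_weight(self):
        img = np.zeros((1, 1, 3), np.uint8)
        img[0, 0] = (255, 0, 0)
        assert pp.to_grayscale(img)[0, 0] == 76  # 0.299 * 255 = 76.245

    def test_all_zero(self):
        assert (pp.to_grayscale(np.zeros((4, 4, 3), np.uint8)) == 0).all()

    def test_single_channel_passthrough_warns(self):
        g = np.arange(16, dtype=np.uint8).reshape(4, 4)
        with pytest.warns(UserWarning):
            out = pp.to_grayscale(g)
        assert (out == g).all()


class TestOtsu:
    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(100):
            h, w = rng.integers(8, 32, size=2)
            kind = rng.integers(3)
            if kind == 0:
                img = rng.integers(0, 256, size=(h, w)).astype(np.uint8)
            elif kind == 1:  # bimodal, kernel-vs-background like
                lo = rng.integers(0, 80, size=(h, w))
                hi = rng.integers(150, 256, size=(h, w))
                img = np.where(rng.random((h, w)) < 0.5, lo, hi).astype(np.uint8)
            else:  # few distinct levels, exercises plateaus
                vals = rng.integers(0, 256, size=3)
                img = vals[rng.integers(0, 3, size=(h, w))].astype(np.uint8)
            if np.unique(img).size < 2:
                continue
            t, _ = pp.otsu_threshold(img)
            assert t == brute_force_otsu(img)

    def test_mean_decomposition_identity(self, rng):
        img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        _, st = pp.otsu_threshold(img)
        valid = (st.omega1 > 0) & (st.omega2 > 0)
        recomposed = (st.omega1 * st.mu1 + st.omega2 * st.mu2)[valid]
        assert np.allclose(recomposed, st.mu, atol=1e-9)

    def test_two_level_tie_breaks_smallest(self):
        img = np.array([[0, 255], [255, 0]], np.uint8)
        t, _ = pp.otsu_threshold(img)
        assert t == 0  # every t in [0, 254] maximizes the criterion

    def test_constant_image_raises(self):
        with pytest.raises(pp.DegenerateHistogramError):
            pp.otsu_threshold(np.full((8, 8), 7, np.uint8))


class TestBinarize:
    def test_uniform_above_threshold(self):
        assert pp.binarize(np.full((3, 3), 200, np.uint8), 100).all()

    def test_uniform_below_threshold(self):
        assert not pp.binarize(np.full((3, 3), 50, np.uint8), 100).any()

    def test_polarity_flag(self):
        img = np.full((2, 2), 50, np.uint8)
        assert pp.binarize(img, 100, bright_foreground=False).all()

    def test_scene_foreground_recovered(self, small_scene):
        spec, image, gt = small_scene
        gray = pp.to_grayscale(image)
        t, _ = pp.otsu_threshold(gray)
        mask = pp.binarize(gray, t)
        true_fg = gt.foreground.sum()
        assert abs(int(mask.sum()) - true_fg) < 0.05 * true_fg


class TestMorphology:
    def test_single_anchor_erosion_is_identity(self, rng):
        m = rng.random((12, 12)) > 0.5
        se = np.zeros((3, 3), bool)
        se[1, 1] = True
        assert (pp.erode(m, se) == m).all()

    def test_dilate_single_pixel_full_se(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        out = pp.dilate(m, np.ones((3, 3), bool))
        expected = np.zeros((7, 7), bool)
        expected[2:5, 2:5] = True
        assert (out == expected).all()

    def test_opening_removes_isolated_pixel(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert not pp.opening(m, np.ones((3, 3), bool)).any()

    def test_empty_structuring_element_raises(self):
        with pytest.raises(ValueError):
            pp.erode(np.ones((4, 4), bool), np.zeros((3, 3), bool))

    @pytest.mark.parametrize("se_shape", ["square", "cross", "ellipse"])
    def test_set_identities_on_random_masks(self, rng, se_shape):
        """Duality, idempotence and the extensivity sandwich, 100 masks each.

        The identities are plane-geometry statements; masks are embedded
        with an empty margin so the image border (treated as background)
        stays out of reach of the structuring element.
        """
        se = pp.structuring_element(se_shape, 3)
        refl = se[::-1, ::-1]
        for _ in range(100):
            m = np.zeros((22, 22), bool)
            m[3:19, 3:19] = rng.random((16, 16)) > rng.uniform(0.3, 0.7)
            inner = (slice(1, -1), slice(1, -1))
            # duality: complement of dilation = erosion of complement by reflection
            assert (~pp.dilate(m, se) == pp.erode(~m, refl))[inner].all()
            opened = pp.opening(m, se)
            assert (pp.opening(opened, se) == opened).all()  # idempotent
            closed = pp.closing(m, se)
            assert (opened <= m).all() and (m <= closed).all()

    def test_agrees_with_scipy_oracle(self, rng):
        """Independent cross-check against scipy.ndimage with zero borders."""
        se = pp.structuring_element("square", 3)
        for _ in range(25):
            m = rng.random((16, 16)) > 0.5
            assert (pp.erode(m, se) == ndimage.binary_erosion(m, se, border_value=0)).all()
            assert (pp.dilate(m, se) == ndimage.binary_dilation(m, se, border_value=0)).all()
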