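"""Sobel gradient, distance transform, marker extraction and flooding."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from kernelseg import watershed as ws
from kernelseg.synthetic import SceneSpec, generate_scene

from conftest import disk_mask


class TestSobel:
    def test_constant_image_zero_gradient(self):
        f = ws.sobel_gradient(np.full((10, 10), 90, np.uint8))
        assert not f.gx.any() and not f.gy.any() and not f.magnitude.any()

    def test_vertical_step_response(self):
        img = np.zeros((10, 10), np.uint8)
        img[:, 5:] = 255
        f = ws.sobel_gradient(img)
        # interior pixel one column left of the edge sees the full 4x255 step
        assert abs(f.gx[5, 4]) == 4 * 255
        assert f.gy[5, 4] == 0

    def test_rotation_swaps_components(self, rng):
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        f = ws.sobel_gradient(img)
        g = ws.sobel_gradient(np.rot90(img))
        inner = slice(2, -2)
        assert np.allclose(
            np.abs(np.rot90(f.gx))[inner, inner], np.abs(g.gy)[inner, inner]
        )


class TestSmoothing:
    def test_constant_field_unchanged(self):
        f = ws.GradientField(np.zeros((8, 8)), np.zeros((8, 8)), np.full((8, 8), 37.0))
        assert np.allclose(ws.smooth_gradient(f).magnitude, 37.0)

    def test_impulse_peaks_at_center_and_symmetric(self):
        m = np.zeros((21, 21))
        m[10, 10] = 255.0
        out = ws.smooth_gradient(ws.GradientField(m * 0, m * 0, m), sigma=1.5).magnitude
        assert np.unravel_index(out.argmax(), out.shape) == (10, 10)
        assert np.allclose(out, out[::-1, :]) and np.allclose(out, out[:, ::-1])

    def test_bad_sigma_raises(self):
        f = ws.GradientField(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            ws.smooth_gradient(f, sigma=0)


class TestDistanceTransform:
    def test_background_is_zero_and_adjacent_is_one(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        d = ws.distance_transform(m)
        assert d[2, 2] == 1.0
        assert (d[~m] == 0).all()

    def test_matches_brute_force_oracle(self, rng):
        """Exact Euclidean distances on 100 random small masks."""
        checked = 0
        while checked < 100:
            h, w = rng.integers(5, 33, size=2)
            m = rng.random((h, w)) > rng.uniform(0.2, 0.8)
            if m.all() or not m.any():
                continue
            d = ws.distance_transform(m)
            fg, bg = np.argwhere(m), np.argwhere(~m)
            brute = np.zeros(m.shape)
            brute[tuple(fg.T)] = cdist(fg, bg).min(axis=1)
            assert np.allclose(d, brute)
            checked += 1

    def test_all_foreground_raises(self):
        with pytest.raises(ValueError):
            ws.distance_transform(np.ones((4, 4), bool))


class TestMarkers:
    def test_two_disjoint_disks_two_markers(self):
        m = disk_mask((80, 160), (40, 40), 25) | disk_mask((80, 160), (40, 120), 25)
        mk = ws.extract_markers(ws.distance_transform(m), m)
        assert mk.max() == 2

    @pytest.mark.parametrize("pf", [0.2, 0.4, 0.7])
    def test_single_disk_one_marker(self, pf):
        m = disk_mask((80, 120), (40, 60), 30)
        mk = ws.extract_markers(ws.distance_transform(m), m, peak_fraction=pf)
        assert mk.max() == 1

    def test_lightly_overlapping_pair_separates(self):
        """A distance ridge forms between barely-fused disks; both cores marked."""
        m = disk_mask((80, 160), (40, 50), 20) | disk_mask((80, 160), (40, 89), 20)
        mk = ws.extract_markers(ws.distance_transform(m), m)
        assert mk.max() == 2

    def test_empty_mask_raises_with_guidance(self):
        with pytest.raises(ValueError, match="peak_fraction"):
            ws.extract_markers(np.zeros((5, 5)), np.zeros((5, 5), bool))


class TestFlood:
    def test_single_marker_floods_whole_foreground(self):
        m = disk_mask((50, 50), (25, 25), 15)
        d = ws.distance_transform(m)
        mk = np.zeros_like(m, dtype=np.int32)
        mk[25, 25] = 1
        lab = ws.watershed_flood(-d, mk, m, keep_lines=False)
        assert set(np.unique(lab[m])) == {1}
        assert (lab[~m] == 0).all()

    def test_symmetric_pair_line_at_axis(self):
        m = disk_mask((80, 160), (40, 60), 20) | disk_mask((80, 160), (40, 99), 20)
        lab = ws.segment_mask(m)
        assert set(np.unique(lab)) == {0, 1, 2}
        # centroid column of the two basins straddles the symmetry axis (~79.5)
        c1 = np.argwhere(lab == 1)[:, 1].max()
        c2 = np.argwhere(lab == 2)[:, 1].min()
        assert abs((c1 + c2) / 2 - 79.5) <= 1.5

    def test_partition_and_marker_conservation(self, small_scene):
        _, image, gt = small_scene
        from kernelseg import preprocess as pp

        gray = pp.to_grayscale(image)
        t, _ = pp.otsu_threshold(gray)
        mask = pp.clean_mask(pp.binarize(gray, t))
        d = ws.distance_transform(mask)
        mk = ws.extract_markers(d, mask)
        lab = ws.watershed_flood(-d, mk, mask, keep_lines=False)
        assert (lab[~mask] == 0).all()
        assert (lab[mask] > 0).all()  # every foreground pixel labelled
        assert set(np.unique(lab)) - {0} == set(np.unique(mk)) - {0}

    def test_marker_outside_mask_raises(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        mk = np.zeros((10, 10), np.int32)
        mk[8, 8] = 1
        with pytest.raises(ValueError):
            ws.watershed_flood(np.zeros((10, 10)), mk, m)


def test_watershed_separates_barely_touching_pairs():
    """Coarse-stage contract: pairs with minimal overlap split by flooding alone."""
    rng = np.random.default_rng(7)
    separated = 0
    n = 30
    for _ in range(n):
        r1, r2 = rng.integers(16, 26, size=2)
        gap = rng.integers(0, 3)  # centers at r1+r2-gap: touching to tiny overlap
        m = disk_mask((120, 220), (60, 60), r1) | disk_mask(
            (120, 220), (60, 60 + r1 + r2 - gap), r2
        )
        lab = ws.segment_mask(m)
        if lab.max() == 2:
            separated += 1
    assert separated >= 0.9 * n
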