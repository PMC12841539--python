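"""Boundary tracing, convex hull, convexity defects and contour cutting."""

import math

import numpy as np
import pytest
from scipy import ndimage

from kernelseg import hull
from conftest import disk_mask


def fused_disks(d_center, r=20, shape=(80, 140)):
    return disk_mask(shape, (40, 50), r) | disk_mask(shape, (40, 50 + d_center), r)


class TestTraceBoundary:
    def test_square_boundary(self):
        m = np.zeros((12, 12), bool)
        m[1:11, 1:11] = True
        c = hull.trace_boundary(m)
        assert len(c) == 36  # 4 * 10 - 4 border pixels
        assert set(map(tuple, c.tolist())) == {
            (r, cc) for r in range(1, 11) for cc in range(1, 11)
            if r in (1, 10) or cc in (1, 10)
        }

    def test_disk_boundary_closed_and_on_rim(self):
        m = disk_mask((50, 50), (25, 25), 18)
        c = hull.trace_boundary(m)
        # the traced boundary is exactly the pixels 4-adjacent to background
        rim4 = m & ~ndimage.binary_erosion(
            m, ndimage.generate_binary_structure(2, 1), border_value=0
        )
        assert set(map(tuple, c.tolist())) == set(map(tuple, np.argwhere(rim4).tolist()))
        steps = np.abs(np.diff(np.vstack([c, c[:1]]), axis=0)).max(axis=1)
        assert (steps == 1).all()  # closed 8-connected cycle

    def test_single_pixel(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert hull.trace_boundary(m).tolist() == [[1, 1]]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hull.trace_boundary(np.zeros((3, 3), bool))


class TestConvexHull:
    def test_square_with_interior_point(self):
        pts = [(0, 0), (0, 4), (4, 4), (4, 0), (2, 2)]
        h = hull.convex_hull(np.array(pts))
        assert set(map(tuple, h.tolist())) == {(0, 0), (0, 4), (4, 4), (4, 0)}

    def test_random_points_halfplane_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(50, 2))
        h = hull.convex_hull(pts)
        n = len(h)
        for k in range(n):
            a, b = h[k], h[(k + 1) % n]
            cross = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
            # every input point on one side of every hull edge
            assert (cross >= -1e-9).all() or (cross <= 1e-9).all()

    def test_collinear_raises(self):
        with pytest.raises(ValueError):
            hull.convex_hull(np.array([(0, 0), (1, 1), (2, 2), (3, 3)]))


class TestDefectDepth:
    @pytest.mark.parametrize(
        "a,b,c,expected",
        [((0, 0), (10, 0), (5, 4), 4.0),
         ((0, 0), (3, 4), (3, 0), 2.4),
         ((0, 0), (10, 0), (7, 0), 0.0)],
    )
    def test_hand_cases(self, a, b, c, expected):
        assert hull.defect_depth(a, b, c) == pytest.approx(expected, abs=1e-12)

    def test_coincident_endpoints_raise(self):
        with pytest.raises(ValueError):
            hull.defect_depth((1, 2), (1, 2), (3, 4))

    def test_matches_projection_formula_on_random_triples(self, rng):
        """Independent oracle: orthogonal-projection residual norm."""
        for _ in range(1000):
            a, b, c = rng.uniform(-50, 50, size=(3, 2))
            if np.allclose(a, b):
                continue
            ab, ac = b - a, c - a
            resid = ac - (ac @ ab) / (ab @ ab) * ab
            assert hull.defect_depth(a, b, c) == pytest.approx(
                math.hypot(*resid), abs=1e-9
            )


class TestFindDefects:
    def test_digital_disk_has_no_deep_defects(self):
        c = hull.trace_boundary(disk_mask((60, 60), (30, 30), 22))
        assert hull.find_defects(c, 8.0) == []

    def test_fused_disks_two_neck_defects(self):
        # center distance 34 px, radius 20: neck depth ~9.4 px on each side
        c = hull.trace_boundary(fused_disks(34))
        defs = hull.find_defects(c, 8.0)
        assert len(defs) == 2
        assert all(d.depth > 8 for d in defs)
        # the two pinch points face each other across the neck
        p1, p2 = defs[0].farthest_point, defs[1].farthest_point
        assert abs(p1[1] - p2[1]) <= 3 and abs(p1[0] - p2[0]) > 10

    def test_infinite_threshold_empty(self):
        c = hull.trace_boundary(fused_disks(34))
        assert hull.find_defects(c, float("inf")) == []

    def test_necks_selected_wrinkles_rejected(self, rng):
        """At the 8 px threshold every adhesion neck and no surface wrinkle fires."""
        necks = wrinkles = neck_hits = wrinkle_hits = 0
        for k in range(12):
            d = int(rng.integers(34, 38))  # neck depths ~9.4-12 px
            c = hull.trace_boundary(fused_disks(d))
            necks += 1
            neck_hits += bool(hull.find_defects(c, 8.0))
        for k in range(12):
            m = disk_mask((60, 60), (30, 30), 22)
            for _ in range(5):  # dents under 5 px: wrinkle-scale concavities
                theta = rng.uniform(0, 2 * math.pi)
                p = (30 + 22 * math.sin(theta), 30 + 22 * math.cos(theta))
                m &= ~disk_mask((60, 60), p, rng.uniform(1.5, 3.5))
            if ndimage.label(m, np.ones((3, 3)))[1] != 1:
                continue
            c = hull.trace_boundary(m)
            wrinkles += 1
            wrinkle_hits += bool(hull.find_defects(c, 8.0))
        assert neck_hits == necks
        assert wrinkle_hits == 0 and wrinkles > 6


class TestSplitAtDefects:
    def test_convex_region_unchanged(self):
        m = disk_mask((50, 50), (25, 25), 18)
        cut, contours = hull.split_at_defects(m)
        assert (cut == m).all()
        assert len(contours) == 1

    def test_fused_pair_splits_into_two_disks(self):
        m = fused_disks(34)
        area0 = m.sum()
        cut, contours = hull.split_at_defects(m)
        assert len(contours) == 2
        single = math.pi * 400
        pieces = ndimage.label(cut, np.ones((3, 3)))[0]
        sizes = np.bincount(pieces.ravel())[1:]
        assert all(abs(s - single) < 0.15 * single for s in sizes)
        # area conserved up to the 1-px-wide cut
        assert area0 - cut.sum() <= 3 * 41  # cut length bounded by disk diameter

    def test_chain_of_three_splits_into_three(self):
        m = np.zeros((80, 200), bool)
        for cx in (50, 84, 118):
            m |= disk_mask((80, 200), (40, cx), 20)
        _, contours = hull.split_at_defects(m)
        assert len(contours) == 3

    def test_never_decreases_count(self, rng):
        for _ in range(10):
            m = np.zeros((70, 140), bool)
            for _ in range(3):
                m |= disk_mask(
                    (70, 140),
                    (rng.integers(20, 50), rng.integers(20, 120)),
                    rng.integers(10, 20),
                )
            n0 = ndimage.label(m, np.ones((3, 3)))[1]
            cut, contours = hull.split_at_defects(m)
            assert len(contours) >= n0


class TestCountObjects:
    def test_empty_list(self):
        assert hull.count_objects([]) == 0

    def test_min_area_filters(self):
        small = hull.trace_boundary(disk_mask((20, 20), (10, 10), 3))
        big = hull.trace_boundary(disk_mask((60, 60), (30, 30), 20))
        assert hull.count_objects([small, big], min_area=100) == 1
        assert hull.count_objects([small, big], min_area=0) == 2

    def test_idempotent(self):
        c = hull.trace_boundary(disk_mask((40, 40), (20, 20), 12))
        assert hull.count_objects([c, c]) == hull.count_objects([c, c])

    def test_polygon_area_matches_pixel_count(self, rng):
        for r in (5, 9, 14):
            m = disk_mask((40, 40), (20, 20), r)
            c = hull.trace_boundary(m)
            assert hull.polygon_pixel_area(c) == pytest.approx(
                m.sum(), abs=0.5 * len(c)
            )
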