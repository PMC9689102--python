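"""Boundary detection, simplification, contour tracing, areas, overlays."""

import numpy as np
import pytest

import cystoseg as cs
from cystoseg.polygons import (Polygon, PolygonConfig, TraceDiagnostics,
                               rasterize)
from cystoseg.scheme import CANCER, DEFAULT_SCHEME, NORMAL


def boundary_oracle(seg):
    """Exhaustive per-pixel 4-neighbour scan (border counts as boundary)."""
    h, w = seg.shape
    out = {}
    for c in np.unique(seg):
        mask = np.zeros((h, w), dtype=bool)
        for r in range(h):
            for cc in range(w):
                if seg[r, cc] != c:
                    continue
                for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                    rr, ccc = r + dr, cc + dc
                    if not (0 <= rr < h and 0 <= ccc < w) or seg[rr, ccc] != c:
                        mask[r, cc] = True
                        break
        out[c] = mask
    return out


def simplify_oracle(seg, max_passes):
    """Direct application of the >4-of-8 removal rule (edge replicate)."""
    seg = seg.copy()
    h, w = seg.shape
    for _ in range(max_passes):
        padded = np.pad(seg, 1, mode="edge")
        flagged, new_class = [], []
        for r in range(h):
            for c in range(w):
                counts = np.zeros(7, dtype=int)
                diff = 0
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        nb = padded[r + 1 + dr, c + 1 + dc]
                        counts[nb] += 1
                        diff += nb != seg[r, c]
                if diff > 4:
                    flagged.append((r, c))
                    new_class.append(int(counts.argmax()))
        if not flagged:
            break
        for (r, c), nc in zip(flagged, new_class):
            seg[r, c] = nc
    return seg


class TestFindBoundaries:
    def test_uniform_map_boundary_is_border_ring(self):
        seg = np.ones((8, 8), dtype=int)
        b = cs.find_boundaries(seg)[1]
        expected = np.zeros((8, 8), dtype=bool)
        expected[0] = expected[-1] = expected[:, 0] = expected[:, -1] = True
        np.testing.assert_array_equal(b, expected)

    def test_isolated_pixel_and_its_neighbours(self):
        seg = np.zeros((9, 9), dtype=int)
        seg[4, 4] = 1
        b = cs.find_boundaries(seg)
        assert b[1][4, 4]
        for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            assert b[0][4 + dr, 4 + dc]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan_oracle(self, seed):
        seg = np.random.default_rng(seed).integers(0, 2, size=(12, 12))
        got = cs.find_boundaries(seg)
        expected = boundary_oracle(seg)
        assert set(got) == set(expected)
        for c in expected:
            np.testing.assert_array_equal(got[c], expected[c])


class TestSimplifyBoundary:
    def test_rectangle_edges_survive_corners_chamfered(self):
        # straight-edge pixels have <= 4 differing 8-neighbours and stay;
        # corner pixels have exactly 5 and are removed by the > 4 rule
        seg = np.zeros((12, 12), dtype=int)
        seg[3:9, 2:10] = 1
        out = cs.simplify_boundary(seg, max_passes=1)
        corners = [(3, 2), (3, 9), (8, 2), (8, 9)]
        for r, c in corners:
            assert out[r, c] == 0
        kept = seg.copy()
        for r, c in corners:
            kept[r, c] = 0
        np.testing.assert_array_equal(out, kept)

    def test_isolated_pixel_removed_in_one_pass(self):
        seg = np.zeros((9, 9), dtype=int)
        seg[4, 4] = 1
        out = cs.simplify_boundary(seg, max_passes=1)
        assert out[4, 4] == 0
        np.testing.assert_array_equal(out, 0)

    def test_diagonal_spike_matches_rule_oracle(self):
        seg = np.zeros((14, 14), dtype=int)
        seg[4:10, 4:10] = 1
        for i in range(3):  # one-pixel-wide diagonal spike
            seg[3 - i, 3 - i] = 1
        out = cs.simplify_boundary(seg, max_passes=2)
        np.testing.assert_array_equal(out, simplify_oracle(seg, 2))
        assert out[0, 0] == 0  # spike tip removed

    @pytest.mark.parametrize("seed", range(4))
    def test_random_maps_match_rule_oracle(self, seed):
        seg = np.random.default_rng(seed).integers(0, 3, size=(10, 10))
        np.testing.assert_array_equal(cs.simplify_boundary(seg, 2),
                                      simplify_oracle(seg, 2))

    def test_region_area_never_increases(self):
        seg = np.zeros((16, 16), dtype=int)
        seg[4:12, 4:12] = 1
        seg[3, 3] = 1
        out = cs.simplify_boundary(seg, 2)
        assert (out == 1).sum() <= (seg == 1).sum()


class TestTraceContour:
    def test_square_region_single_loop_of_border_pixels(self):
        seg = np.zeros((8, 8), dtype=int)
        seg[2:6, 2:6] = 1
        polys, diag = cs.trace_contour(cs.find_boundaries(seg), 1)
        assert len(polys) == 1
        assert len(polys[0]) == 12  # the 4x4 square's border ring
        expected = {(r, c) for r in range(2, 6) for c in range(2, 6)
                    if r in (2, 5) or c in (2, 5)}
        assert set(polys[0].vertices) == expected
        assert diag.n_noise_pixels == 0

    def test_two_disjoint_regions_give_two_polygons(self):
        seg = np.zeros((16, 16), dtype=int)
        seg[1:5, 1:5] = 1
        seg[9:14, 9:14] = 1
        polys, _ = cs.trace_contour(cs.find_boundaries(seg), 1)
        assert len(polys) == 2

    def test_two_pixel_fragment_discarded_as_noise(self):
        seg = np.zeros((8, 8), dtype=int)
        seg[3, 3:5] = 1
        polys, diag = cs.trace_contour(cs.find_boundaries(seg), 1)
        assert polys == []
        assert diag.n_noise_chains == 1
        assert diag.n_noise_pixels == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_pixel_conservation_on_random_maps(self, seed):
        seg = np.random.default_rng(seed).integers(0, 3, size=(32, 32))
        boundary = cs.find_boundaries(seg)
        for c in boundary:
            n_boundary = int(boundary[c].sum())
            polys, diag = cs.trace_contour(boundary, c)
            n_vertices = sum(len(p) for p in polys)
            assert n_vertices + diag.n_noise_pixels == n_boundary

    def test_emitted_loops_are_closed_within_search_radius(self, rng):
        seg = rng.integers(0, 2, size=(24, 24))
        boundary = cs.find_boundaries(seg)
        for c in boundary:
            polys, _ = cs.trace_contour(boundary, c)
            for p in polys:
                v = np.array(p.vertices)
                gaps = np.abs(v - np.roll(v, -1, axis=0)).max(axis=1)
                assert gaps.max() <= 5


class TestShoelaceArea:
    def test_unit_square(self):
        assert cs.shoelace_area([(0, 0), (0, 1), (1, 1), (1, 0)]) == 1.0

    def test_orientation_independent(self):
        verts = [(0, 0), (0, 4), (3, 4), (3, 0)]
        assert cs.shoelace_area(verts) == cs.shoelace_area(verts[::-1]) == 12.0

    def test_degenerate_polygon_has_zero_area(self):
        assert cs.shoelace_area([(0, 0), (1, 1)]) == 0.0

    def test_translation_invariant_and_quadratic_scaling(self, rng):
        verts = [(2, 1), (1, 5), (4, 8), (7, 6), (6, 2)]
        a = cs.shoelace_area(verts)
        shifted = [(r + 11, c + 3) for r, c in verts]
        assert cs.shoelace_area(shifted) == pytest.approx(a)
        scaled = [(3 * r, 3 * c) for r, c in verts]
        assert cs.shoelace_area(scaled) == pytest.approx(9 * a)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_hexagon_matches_monte_carlo_oracle(self, seed):
        g = np.random.default_rng(seed)
        angles = np.sort(g.uniform(0, 2 * np.pi, 6))
        radii = g.uniform(10, 30, 6)
        verts = [(int(round(40 + r * np.sin(a))), int(round(40 + r * np.cos(a))))
                 for a, r in zip(angles, radii)]
        area = cs.shoelace_area(verts)
        import shapely
        poly = shapely.Polygon([(c, r) for r, c in verts])
        pts = g.uniform(0, 80, size=(40000, 2))
        inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        mc = inside.mean() * 80 * 80
        assert area == pytest.approx(mc, rel=0.02)


class TestFilterSmall:
    def _poly_with_area(self, side):
        return Polygon([(0, 0), (0, side), (side, side), (side, 0)], CANCER)

    def test_area_63_discarded_on_160_map(self):
        # sqrt(63) x sqrt(63) square is below the 64 px threshold
        p = Polygon([(0, 0), (0, 9), (7, 9), (7, 0)], CANCER)  # area 63
        assert cs.shoelace_area(p) == 63.0
        assert cs.filter_small([p], (160, 160)) == []

    def test_area_64_kept_inclusive_threshold(self):
        p = self._poly_with_area(8)  # area 64
        assert cs.filter_small([p], (160, 160)) == [p]

    def test_zero_fraction_keeps_everything(self):
        p = self._poly_with_area(1)
        assert cs.filter_small([p], (160, 160), min_fraction=0.0) == [p]

    def test_idempotent(self, rng):
        polys = [self._poly_with_area(s) for s in (3, 8, 20)]
        once = cs.filter_small(polys, (160, 160))
        twice = cs.filter_small(once, (160, 160))
        assert once == twice


class TestRenderOverlay:
    def test_empty_polygon_list_is_identity(self, rng):
        img = rng.random((16, 16, 3))
        np.testing.assert_array_equal(cs.render_overlay(img, []), img)

    def test_cancer_loop_recolored_cyan_only(self, rng):
        img = rng.random((20, 20, 3)) * 0.5
        poly = Polygon([(2, 2), (2, 10), (10, 10), (10, 2)], CANCER)
        out = cs.render_overlay(img, [poly])
        changed = np.any(out != img, axis=2)
        from skimage.draw import line
        expected = np.zeros((20, 20), dtype=bool)
        verts = poly.vertices
        for i in range(4):
            rr, cc = line(*verts[i], *verts[(i + 1) % 4])
            expected[rr, cc] = True
        np.testing.assert_array_equal(changed, expected)
        assert np.all(out[changed] == DEFAULT_SCHEME.color_of[CANCER])


class TestSegmapToPolygons:
    def test_all_normal_map_gives_empty_list(self):
        polys, _ = cs.segmap_to_polygons(np.zeros((32, 32), dtype=int))
        assert polys == []

    def test_single_lesion_gives_single_cancer_polygon(self):
        seg = np.zeros((64, 64), dtype=int)
        rr, cc = np.mgrid[0:64, 0:64]
        seg[((rr - 32) / 14) ** 2 + ((cc - 30) / 10) ** 2 <= 1] = CANCER
        polys, _ = cs.segmap_to_polygons(seg)
        assert len(polys) == 1
        assert polys[0].class_index == CANCER

    def test_speckle_filtered_lesion_kept(self):
        seg = np.zeros((160, 160), dtype=int)
        rr, cc = np.mgrid[0:160, 0:160]
        seg[((rr - 60) / 13) ** 2 + ((cc - 60) / 11) ** 2 <= 1] = CANCER  # ~450 px
        seg[120:124, 120:125] = CANCER  # 20 px speckle, below 64 px threshold
        polys, _ = cs.segmap_to_polygons(seg)
        assert len(polys) == 1
        assert cs.shoelace_area(polys[0]) >= 64

    def test_round_trip_dice_on_convex_region(self):
        seg = np.zeros((160, 160), dtype=int)
        rr, cc = np.mgrid[0:160, 0:160]
        region = ((rr - 80) / 16) ** 2 + ((cc - 76) / 12) ** 2 <= 1
        seg[region] = CANCER
        polys, _ = cs.segmap_to_polygons(seg)
        assert len(polys) == 1
        recovered = rasterize(polys[0], seg.shape)
        inter = (recovered & region).sum()
        d = 2 * inter / (recovered.sum() + region.sum())
        assert d >= 0.9
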