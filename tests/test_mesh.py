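"""Geometry, boundary topology and snapshot round-trip of the cell mesh."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from epivertex.mesh import (
    Cell,
    MeshError,
    SnapshotError,
    TissueState,
    boundary_edges,
    cell_area,
    cell_centroid,
    cell_perimeter,
    polygon_area,
    read_snapshot,
    tissue_boundary_polygon,
    validate,
    write_snapshot,
)
from epivertex.scenarios import make_hex_patch, make_periodic_patch


def convex_polygon_tissue(n, seed):
    """Random convex n-gon (convex hull of random points)."""
    rng = np.random.default_rng(seed)
    while True:
        pts = rng.normal(size=(n + 6, 2))
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        if len(hull.vertices) >= n:
            coords = pts[hull.vertices[:n]] if len(hull.vertices) > n else pts[hull.vertices]
            if polygon_area(coords) < 0:
                coords = coords[::-1]
            return TissueState(
                vertices=coords, cells={0: Cell(vertices=list(range(len(coords))))}
            )


class TestGeometry:
    def test_unit_square(self, unit_square):
        assert cell_area(unit_square, 0) == pytest.approx(1.0)
        assert cell_perimeter(unit_square, 0) == pytest.approx(4.0)
        assert cell_centroid(unit_square, 0) == pytest.approx([0.5, 0.5])

    def test_regular_hexagon(self, hexagon):
        assert cell_area(hexagon, 0) == pytest.approx(3 * np.sqrt(3) / 2)
        assert cell_perimeter(hexagon, 0) == pytest.approx(6.0)

    def test_triangle_centroid(self):
        t = TissueState(
            vertices=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            cells={0: Cell(vertices=[0, 1, 2])},
        )
        assert cell_centroid(t, 0) == pytest.approx([1 / 3, 1 / 3])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_area_matches_triangulation_fan(self, seed):
        t = convex_polygon_tissue(7, seed)
        coords = t.vertices
        # independent oracle: fan triangulation from vertex 0
        fan = 0.0
        for i in range(1, len(coords) - 1):
            a, b, c = coords[0], coords[i], coords[i + 1]
            fan += 0.5 * abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
        assert cell_area(t, 0) == pytest.approx(fan, abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_perimeter_matches_pairwise_sum(self, seed):
        t = convex_polygon_tissue(6, seed)
        coords = t.vertices
        total = sum(
            np.hypot(*(coords[(i + 1) % len(coords)] - coords[i])) for i in range(len(coords))
        )
        assert cell_perimeter(t, 0) == pytest.approx(total, abs=1e-12)

    def test_geometry_matches_shapely(self):
        t = convex_polygon_tissue(7, 11)
        poly = Polygon(t.vertices)
        assert cell_area(t, 0) == pytest.approx(poly.area, rel=1e-12)
        assert cell_perimeter(t, 0) == pytest.approx(poly.exterior.length, rel=1e-12)
        g = cell_centroid(t, 0)
        assert g == pytest.approx([poly.centroid.x, poly.centroid.y], abs=1e-12)

    def test_centroid_matches_monte_carlo(self):
        t = convex_polygon_tissue(7, 5)
        poly = Polygon(t.vertices)
        rng = np.random.default_rng(0)
        minx, miny, maxx, maxy = poly.bounds
        pts = rng.uniform([minx, miny], [maxx, maxy], size=(60000, 2))
        from shapely import points, contains

        inside = pts[contains(poly, points(pts))]
        mc = inside.mean(axis=0)
        assert cell_centroid(t, 0) == pytest.approx(mc, abs=0.02)

    def test_vertex_mean_centroid_switch(self, unit_square):
        assert cell_centroid(unit_square, 0, mode="vertex") == pytest.approx([0.5, 0.5])
        with pytest.raises(ValueError):
            cell_centroid(unit_square, 0, mode="nope")

    def test_degenerate_cell_rejected(self):
        t = TissueState(
            vertices=np.array([[0.0, 0.0], [1.0, 0.0]]), cells={0: Cell(vertices=[0, 1])}
        )
        with pytest.raises(MeshError):
            cell_area(t, 0)


class TestBoundary:
    def test_single_hexagon_all_edges_boundary(self, hexagon):
        assert len(boundary_edges(hexagon)) == 6

    def test_hex_rosette_outer_edges(self):
        # 7-cell honeycomb rosette: each of the 6 petals keeps 3 outer
        # edges (it shares one with the center and two with its petal
        # neighbors), giving 18 boundary edges
        patch = make_hex_patch(3, 3)
        nmap = patch.neighbors()
        center = next(c for c in patch.cells if len(nmap[c]) == 6)
        keep = [center] + sorted(nmap[center])
        rosette = TissueState(
            vertices=patch.vertices.copy(),
            cells={cid: patch.cells[cid] for cid in keep},
        )
        assert len(boundary_edges(rosette)) == 18
        validate(rosette)

    def test_periodic_patch_has_no_boundary(self):
        patch = make_periodic_patch(4, 4)
        assert boundary_edges(patch) == set()

    def test_disconnected_tissue_rejected(self):
        t = TissueState(
            vertices=np.array(
                [[0, 0], [1, 0], [1, 1], [0, 1], [5, 5], [6, 5], [6, 6], [5, 6]], float
            ),
            cells={0: Cell(vertices=[0, 1, 2, 3]), 1: Cell(vertices=[4, 5, 6, 7])},
        )
        with pytest.raises(MeshError):
            boundary_edges(t)

    def test_cell_areas_sum_to_boundary_loop_area(self, circle_tissue):
        total = sum(cell_area(circle_tissue, c) for c in circle_tissue.cells)
        outline = polygon_area(tissue_boundary_polygon(circle_tissue))
        assert total == pytest.approx(outline, rel=1e-9)

    def test_fixture_passes_full_validation(self, circle_tissue):
        validate(circle_tissue)  # edge sharing, orientation, boundary loop


class TestSnapshot:
    def test_round_trip_is_bit_exact(self, tmp_path, circle_tissue):
        path = tmp_path / "snap.json"
        write_snapshot(circle_tissue, path)
        back = read_snapshot(path)
        assert np.array_equal(back.vertices, circle_tissue.vertices)
        assert back.time == circle_tissue.time
        for cid, cell in circle_tissue.cells.items():
            b = back.cells[cid]
            assert b.vertices == cell.vertices
            assert (b.A0, b.K, b.gamma, b.V, b.c, b.region, b.active) == (
                cell.A0, cell.K, cell.gamma, cell.V, cell.c, cell.region, cell.active,
            )

    def test_missing_vertex_reference_rejected(self, tmp_path, unit_square):
        path = tmp_path / "snap.json"
        write_snapshot(unit_square, path)
        import json

        doc = json.loads(path.read_text())
        doc["cells"]["0"]["vertex_cycle"] = [0, 1, 99]
        path.write_text(json.dumps(doc))
        with pytest.raises(SnapshotError, match="out of range"):
            read_snapshot(path)

    def test_version_mismatch_rejected(self, tmp_path, unit_square):
        path = tmp_path / "snap.json"
        write_snapshot(unit_square, path)
        import json

        doc = json.loads(path.read_text())
        doc["meta"]["version"] = "99"
        path.write_text(json.dumps(doc))
        with pytest.raises(SnapshotError, match="version"):
            read_snapshot(path)


class TestGeometryProperties:
    """Property tests over random convex polygons (hypothesis)."""

    @staticmethod
    def _tissue_from_points(pts):
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        coords = pts[hull.vertices]
        if polygon_area(coords) < 0:
            coords = coords[::-1]
        return TissueState(
            vertices=coords, cells={0: Cell(vertices=list(range(len(coords))))}
        )

    def _check(self, pts):
        import pytest as _pytest

        pts = np.asarray(pts, dtype=float)
        if len(np.unique(pts.round(6), axis=0)) < 4:
            return
        t = self._tissue_from_points(pts)
        poly = Polygon(t.vertices)
        assert cell_area(t, 0) > 0
        assert cell_area(t, 0) == _pytest.approx(poly.area, rel=1e-9)
        assert cell_perimeter(t, 0) == _pytest.approx(poly.exterior.length, rel=1e-9)
        g = cell_centroid(t, 0)
        assert poly.buffer(1e-9).contains(__import__("shapely").geometry.Point(g))

    def test_shoelace_properties_match_reference_geometry(self):
        from hypothesis import given, settings, strategies as st

        coord = st.floats(min_value=-50, max_value=50, allow_nan=False)
        points = st.lists(st.tuples(coord, coord), min_size=5, max_size=12)

        @settings(derandomize=True, max_examples=30, deadline=None)
        @given(points)
        def run(pts):
            self._check(pts)

        run()
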