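"""Mesh volumetrics and linear measurement tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paleoneuro import (
    MeshError,
    OpenMeshWarning,
    Polyline,
    TriangleMesh,
    linear_distance,
    load_mesh,
    make_ellipsoid_mesh,
    mesh_volume,
    polyline_length,
    save_stl,
)
from conftest import make_cube


class TestMeshVolume:
    def test_cube_closed_form(self, cube):
        assert mesh_volume(cube) == pytest.approx(1.0, rel=1e-12)

    def test_tetrahedron_determinant(self):
        v = np.array(
            [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float
        )
        f = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        tet = TriangleMesh(v, f)
        assert mesh_volume(tet) == pytest.approx(1000.0 / 6.0 / 1000.0, rel=1e-12)

    def test_icosphere_close_to_analytic_sphere(self):
        result = make_ellipsoid_mesh(10.0, 10.0, 10.0, subdivisions=4)
        vol = mesh_volume(result.mesh)
        true = 4.0 / 3.0 * math.pi  # cm^3
        assert abs(vol - true) / true < 0.005

    def test_agrees_with_trimesh_oracle(self):
        import trimesh

        result = make_ellipsoid_mesh(12.0, 7.0, 4.0, subdivisions=3)
        ours = mesh_volume(result.mesh)
        theirs = trimesh.Trimesh(
            vertices=result.mesh.vertices, faces=result.mesh.faces
        ).volume / 1000.0
        assert ours == pytest.approx(theirs, rel=1e-12)

    def test_rigid_motion_invariance(self, cube):
        rng = np.random.default_rng(42)
        base = mesh_volume(cube)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            shifted = cube.vertices @ q.T + rng.normal(scale=50.0, size=3)
            moved = TriangleMesh(shifted, cube.faces)
            assert mesh_volume(moved) == pytest.approx(base, rel=1e-9)

    def test_disjoint_components_are_additive(self):
        a = make_cube(side=10.0)
        b = make_cube(side=5.0, origin=(100.0, 0.0, 0.0))
        merged = TriangleMesh(
            np.vstack([a.vertices, b.vertices]),
            np.vstack([a.faces, b.faces + len(a.vertices)]),
        )
        assert mesh_volume(merged) == pytest.approx(
            mesh_volume(a) + mesh_volume(b), rel=1e-12
        )

    def test_reversed_winding_same_magnitude(self, cube):
        flipped = TriangleMesh(cube.vertices, cube.faces[:, ::-1])
        assert mesh_volume(flipped) == pytest.approx(mesh_volume(cube), rel=1e-12)

    def test_one_inverted_face_is_repaired(self, cube):
        faces = cube.faces.copy()
        faces[3] = faces[3][::-1]
        assert mesh_volume(TriangleMesh(cube.vertices, faces)) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_open_mesh_error_names_boundary_count(self, cube):
        holed = TriangleMesh(cube.vertices, cube.faces[:-1])
        with pytest.raises(MeshError, match="3 boundary edges"):
            mesh_volume(holed)

    def test_open_mesh_permissive_warns(self, cube):
        holed = TriangleMesh(cube.vertices, cube.faces[:-1])
        with pytest.warns(OpenMeshWarning):
            vol = mesh_volume(holed, permissive=True)
        assert vol > 0

    def test_face_index_out_of_range_rejected(self):
        with pytest.raises(MeshError, match="missing vertices"):
            TriangleMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))

    def test_nonfinite_vertices_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [np.nan, 1, 0]])
        with pytest.raises(MeshError, match="finite"):
            TriangleMesh(v, np.array([[0, 1, 2]]))

    def test_stl_round_trip(self, cube, tmp_path):
        path = tmp_path / "cube.stl"
        save_stl(cube, path)
        back = load_mesh(path)
        assert mesh_volume(back) == pytest.approx(1.0, rel=1e-9)


class TestLinearMeasurements:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            ((0, 0, 0), (3, 4, 0), 5.0),
            ((1, 2, 3), (1, 2, 3), 0.0),
            ((1, 2, 3), (4, 6, 3), 5.0),
        ],
    )
    def test_distance_examples(self, p, q, expected):
        assert linear_distance(p, q) == pytest.approx(expected)
        assert linear_distance(q, p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0, 0), (10, 0, 0)], 10.0),
            ([(0, 0, 0), (3, 4, 0), (3, 4, 12)], 17.0),
        ],
    )
    def test_polyline_examples(self, points, expected):
        assert polyline_length(np.array(points, float)) == pytest.approx(expected)

    def test_quarter_circle_arc_length(self):
        theta = np.linspace(0.0, math.pi / 2.0, 100)
        pts = np.column_stack(
            [10.0 * np.cos(theta), 10.0 * np.sin(theta), np.zeros_like(theta)]
        )
        length = polyline_length(pts)
        assert abs(length - 5.0 * math.pi) / (5.0 * math.pi) < 1e-3

    def test_polyline_needs_two_points(self):
        with pytest.raises(ValueError, match="at least 2"):
            Polyline(np.array([[0.0, 0.0, 0.0]]))

    @given(
        st.lists(
            st.tuples(*[st.floats(-100, 100) for _ in range(3)]),
            min_size=2,
            max_size=8,
        ),
        st.integers(min_value=1, max_value=6),
        st.floats(0.01, 0.99),
    )
    def test_length_monotone_under_point_insertion(self, pts, idx, frac):
        """Inserting any point along the path never shortens it."""
        pts = np.array(pts, dtype=float)
        idx = min(idx, len(pts) - 1)
        extra = pts[idx - 1] + frac * (pts[idx] - pts[idx - 1]) + np.array(
            [0.0, 0.0, 1.0]
        )
        longer = np.insert(pts, idx, extra, axis=0)
        assert polyline_length(longer) >= polyline_length(pts) - 1e-9

    def test_polyline_at_least_endpoint_distance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(20, 3)) * 10.0
        assert polyline_length(pts) >= linear_distance(pts[0], pts[-1])
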