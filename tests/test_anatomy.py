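"""Mesh construction, rigid displacement, normals and surface file I/O."""

import numpy as np
import pytest
import trimesh as _trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from megdeep.anatomy import (GeometryConfig, GeometryError, MeshParseError,
                             TriMesh, build_synthetic_anatomy, displace_mesh,
                             load_mesh, mean_edge_length, mesh_stats,
                             points_inside_surface, read_ply, save_mesh,
                             signed_volume, vertex_normals, write_ply)


def ray_cast_inside(points, mesh):
    """Brute-force oracle: crossing parity of a +x ray against every
    triangle (Moller-Trumbore)."""
    v, f = mesh.vertices, mesh.faces
    out = []
    d = np.array([1.0, 0.0, 0.0])
    for p in np.atleast_2d(points):
        hits = 0
        for tri in f:
            a, b, c = v[tri]
            e1, e2 = b - a, c - a
            h = np.cross(d, e2)
            det = e1 @ h
            if abs(det) < 1e-12:
                continue
            s = (p - a) / det
            u = s @ h
            q = np.cross(s * det, e1) / det
            vv = d @ q
            t = e2 @ q
            if 0 <= u <= 1 and 0 <= vv and u + vv <= 1 and t > 1e-9:
                hits += 1
        out.append(hits % 2 == 1)
    return np.array(out)


class TestTriMesh:
    def test_face_index_out_of_range_rejected(self):
        with pytest.raises(GeometryError, match="out of range"):
            TriMesh(np.zeros((3, 3)), np.array([[0, 1, 3]]), "cortex")

    def test_degenerate_face_rejected(self):
        with pytest.raises(GeometryError, match="degenerate"):
            TriMesh(np.eye(3), np.array([[0, 1, 1]]), "cortex")


class TestDisplacement:
    def test_zero_distance_is_identity(self, tetra):
        out = displace_mesh(tetra, np.array([0.0, 1.0, 0.0]), 0.0)
        assert np.array_equal(out.vertices, tetra.vertices)

    def test_forward_backward_inverse_pair(self, tetra):
        ax = np.array([0.0, 1.0, 0.0])
        back = displace_mesh(displace_mesh(tetra, ax, 3.0), ax, -3.0)
        assert np.allclose(back.vertices, tetra.vertices, atol=1e-9)

    def test_centroid_moves_by_distance_times_axis(self, tetra):
        ax = np.array([0.0, 0.0, 1.0])
        out = displace_mesh(tetra, ax, 2.5)
        shift = out.vertices.mean(0) - tetra.vertices.mean(0)
        assert np.allclose(shift, 2.5 * ax)

    def test_non_unit_axis_rejected(self, tetra):
        with pytest.raises(ValueError, match="unit"):
            displace_mesh(tetra, np.array([0.0, 2.0, 0.0]), 1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3),
           st.floats(-20, 20))
    def test_displacement_preserves_edge_lengths(self, axis, dist):
        axis = np.asarray(axis)
        n = np.linalg.norm(axis)
        if n < 1e-3:
            return
        mesh = build_synthetic_anatomy(seed=1).mesh("amygdala_L")
        out = displace_mesh(mesh, axis / n, dist)
        assert np.isclose(mean_edge_length(out), mean_edge_length(mesh),
                          rtol=1e-12)


class TestVertexNormals:
    def test_icosphere_normals_radial(self):
        ico = _trimesh.creation.icosphere(3, radius=10.0)
        mesh = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces), "cortex")
        n = vertex_normals(mesh)
        r = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip((n * r).sum(1), -1, 1)))
        assert ang.max() < 2.0

    def test_unit_norm(self, tetra):
        n = vertex_normals(tetra)
        assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-12)

    def test_winding_reversal_flips_normals(self, tetra):
        flipped = TriMesh(tetra.vertices, tetra.faces[:, ::-1], "cortex")
        assert np.allclose(vertex_normals(flipped), -vertex_normals(tetra))

    def test_matches_per_face_cross_product_oracle(self, tetra):
        # accumulate raw cross products by hand
        v, f = tetra.vertices, tetra.faces
        acc = np.zeros_like(v)
        for tri in f:
            fn = np.cross(v[tri[1]] - v[tri[0]], v[tri[2]] - v[tri[0]])
            for k in tri:
                acc[k] += fn
        acc /= np.linalg.norm(acc, axis=1, keepdims=True)
        assert np.allclose(vertex_normals(tetra), acc)

    def test_isolated_vertex_raises(self):
        v = np.vstack([np.eye(3), [5.0, 5.0, 5.0]])
        with pytest.raises(GeometryError, match="no adjacent face"):
            vertex_normals(TriMesh(v, np.array([[0, 1, 2]]), "cortex"))


class TestSyntheticAnatomy:
    def test_deterministic_given_seed(self):
        a = build_synthetic_anatomy(seed=3)
        b = build_synthetic_anatomy(seed=3)
        for ma, mb in zip(a.meshes, b.meshes):
            assert np.array_equal(ma.vertices, mb.vertices)
            assert np.array_equal(ma.faces, mb.faces)

    def test_no_deep_structures_config(self):
        m = build_synthetic_anatomy(GeometryConfig(include_deep=False), seed=0)
        assert m.labels == ["cortex"]
        assert all(lbl == "cortex" for lbl, _ in m.region_of_vertex)

    def test_mean_edge_lengths_near_targets(self, anatomy):
        cortex = mean_edge_length(anatomy.mesh("cortex"))
        hip = mean_edge_length(anatomy.mesh("hippocampus_L"))
        assert abs(cortex - 4.5) / 4.5 < 0.2
        assert abs(hip - 3.5) / 3.5 < 0.2

    def test_deep_meshes_strictly_inside_cortex(self, anatomy):
        cortex = anatomy.mesh("cortex")
        for m in anatomy.meshes[1:]:
            assert points_inside_surface(m.vertices, cortex).all()

    def test_inside_test_agrees_with_ray_cast_oracle(self, anatomy):
        cortex = anatomy.mesh("cortex")
        rng = np.random.default_rng(0)
        pts = rng.uniform(-45, 45, size=(40, 3))
        assert np.array_equal(points_inside_surface(pts, cortex),
                              ray_cast_inside(pts, cortex))

    def test_deep_volumes_match_analytic_ellipsoid(self, anatomy):
        cfg = GeometryConfig()
        for label, axes in (("hippocampus_L", cfg.hippocampus_axes),
                            ("amygdala_R", cfg.amygdala_axes)):
            vol = signed_volume(anatomy.mesh(label))
            target = 4.0 / 3.0 * np.pi * np.prod(axes)
            assert vol > 0
            assert abs(vol - target) / target < 0.3

    def test_deep_structure_outside_shell_rejected(self):
        cfg = GeometryConfig(hippocampus_center=(60.0, 0.0, 0.0))
        with pytest.raises(GeometryError, match="inside"):
            build_synthetic_anatomy(cfg, seed=0)

    def test_region_map_partitions_vertices(self, anatomy):
        assert len(anatomy.region_of_vertex) == anatomy.n_vertices
        counts = {}
        for lbl, _ in anatomy.region_of_vertex:
            counts[lbl] = counts.get(lbl, 0) + 1
        for m in anatomy.meshes:
            assert counts[m.label] == m.n_vertices


class TestMeshIO:
    def test_ply_roundtrip_bit_identical(self, tetra, tmp_path):
        p = tmp_path / "tetra.ply"
        write_ply(p, tetra)
        back = read_ply(p)
        assert np.array_equal(back.vertices, tetra.vertices)
        assert np.array_equal(back.faces, tetra.faces)
        assert back.label == tetra.label

    def test_ply_header_count_matches_independent_parse(self, tetra, tmp_path):
        p = tmp_path / "tetra.ply"
        write_ply(p, tetra)
        txt = p.read_text().splitlines()
        n = next(int(l.split()[-1]) for l in txt if l.startswith("element vertex"))
        assert n == read_ply(p).n_vertices == 4

    def test_ply_face_index_out_of_range_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.ply"
        p.write_text("ply\nformat ascii 1.0\nelement vertex 2\n"
                     "property double x\nproperty double y\nproperty double z\n"
                     "element face 1\nproperty list uchar int vertex_indices\n"
                     "end_header\n0 0 0\n1 0 0\n3 0 1 5\n")
        with pytest.raises(MeshParseError, match="out of range"):
            read_ply(p)

    def test_empty_face_list_rejected(self, tetra, tmp_path):
        empty = TriMesh(tetra.vertices, np.zeros((0, 3), int), "cortex")
        with pytest.raises(MeshParseError):
            write_ply(tmp_path / "x.ply", empty)

    def test_gifti_roundtrip(self, tetra, tmp_path):
        p = tmp_path / "tetra.surf.gii"
        save_mesh(p, tetra)
        back = load_mesh(p)
        assert np.array_equal(back.vertices, tetra.vertices)
        assert np.array_equal(back.faces, tetra.faces)
        assert back.label == "cortex"

    def test_mesh_stats_fields(self, tetra):
        s = mesh_stats(tetra)
        assert s.vertex_count == 4
        assert s.mean_edge_length == pytest.approx(2 * np.sqrt(2))
        assert s.volume == pytest.approx(8.0 / 3.0)
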