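"""Mesh generation, validation and on-disk round trips."""

import numpy as np
import pytest

import hemoflow as hf
from hemoflow.mesh import DOFMap, read_msh, validate_mesh, write_mesh


@pytest.fixture(scope="module")
def stenosis_mesh():
    geom = hf.build_channel(hf.StenosisSpec())
    return hf.mesh_channel(geom, h_far=0.5, h_lesion=0.2)


class TestMeshChannel:
    def test_rectangle_boundary_tag_lengths_sum_to_perimeter(self, straight_mesh):
        mesh = straight_mesh
        total = 0.0
        by_tag = {"inlet": 0.0, "outlet": 0.0, "wall": 0.0}
        for (a, b, _), tag in zip(mesh.boundary_edges, mesh.boundary_tags):
            ln = np.linalg.norm(mesh.coords[a] - mesh.coords[b])
            by_tag[tag] += ln
            total += ln
        assert by_tag["inlet"] == pytest.approx(2.0)
        assert by_tag["outlet"] == pytest.approx(2.0)
        assert total == pytest.approx(2 * 16 + 2 * 2)

    def test_all_triangles_positive_area(self, stenosis_mesh):
        assert np.all(stenosis_mesh.signed_areas() > 0)

    def test_at_least_six_layers_across_each_throat(self, stenosis_mesh):
        # count vertical mesh layers crossing the throat line x = 7
        md = stenosis_mesh.metadata
        assert md["ny"] >= 6
        i = int(np.argmin(np.abs(md["x_stations"] - 7.0)))
        col = md["corner_grid"][i]
        ys = stenosis_mesh.coords[col, 1]
        assert len(ys) - 1 >= 6
        # narrowest gap over all stations equals the throat gap D - 2 eps
        gaps = [
            stenosis_mesh.coords[md["corner_grid"][k, -1], 1]
            - stenosis_mesh.coords[md["corner_grid"][k, 0], 1]
            for k in range(len(md["x_stations"]))
        ]
        assert min(gaps) == pytest.approx(1.0, abs=0.01)

    def test_refinement_band_finer_than_far_field(self, stenosis_mesh):
        xs = stenosis_mesh.metadata["x_stations"]
        dx = np.diff(xs)
        mids = 0.5 * (xs[:-1] + xs[1:])
        in_lesion = (np.abs(mids - 7.0) < 0.5) | (np.abs(mids - 9.0) < 0.5)
        assert dx[in_lesion].max() < dx[~in_lesion].max()

    def test_halving_h_at_least_quadruples_refined_triangles(self):
        geom = hf.build_channel(hf.StenosisSpec())
        # spacings chosen to divide every mesh segment exactly, so halving h
        # doubles both the axial and transverse counts
        coarse = hf.mesh_channel(geom, h_far=0.5, h_lesion=0.25)
        fine = hf.mesh_channel(geom, h_far=0.25, h_lesion=0.125)
        assert fine.n_elements >= 4 * coarse.n_elements

    def test_deterministic(self):
        geom = hf.build_channel(hf.StenosisSpec())
        m1 = hf.mesh_channel(geom, h_far=0.5, h_lesion=0.2)
        m2 = hf.mesh_channel(geom, h_far=0.5, h_lesion=0.2)
        assert m1.content_hash() == m2.content_hash()

    def test_unresolvable_throat_raises_with_required_h(self):
        geom = hf.build_channel(hf.StenosisSpec(eps=0.98))
        with pytest.raises(ValueError, match="need h_lesion"):
            hf.mesh_channel(geom, h_far=0.5, h_lesion=0.5)

    def test_h_ordering_enforced(self, straight_geom):
        with pytest.raises(ValueError):
            hf.mesh_channel(straight_geom, h_far=0.2, h_lesion=0.4)


class TestValidateMesh:
    def test_clean_mesh_has_no_violations(self, stenosis_mesh):
        report = validate_mesh(stenosis_mesh)
        assert report.ok, report.violations
        assert report.min_area > 0
        assert report.min_angle_deg > 5.0

    def test_perturbed_midside_detected(self, straight_mesh):
        import copy

        bad = copy.deepcopy(straight_mesh)
        bad.coords = bad.coords.copy()
        bad.coords[bad.tris[0, 3]] += 0.01
        report = validate_mesh(bad)
        assert any("midside" in v for v in report.violations)

    def test_euler_relation_on_random_delaunay(self):
        # independent oracle: V - E + F computed on a scipy Delaunay corner
        # graph of random points in the unit square
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(7)
        pts = np.vstack([rng.random((40, 2)), [[0, 0], [0, 1], [1, 0], [1, 1]]])
        tri = Delaunay(pts)
        edges = set()
        for t in tri.simplices:
            for i, j in ((0, 1), (1, 2), (2, 0)):
                a, b = sorted((t[i], t[j]))
                edges.add((a, b))
        euler = len(pts) - len(edges) + len(tri.simplices)
        assert euler == 1


class TestDOFMap:
    def test_pressure_only_on_corners(self, straight_mesh):
        dm = DOFMap(straight_mesh.n_nodes, straight_mesh.n_corners)
        with pytest.raises(ValueError):
            dm.field_dofs("p", np.array([straight_mesh.n_corners]))

    def test_indices_dense_and_disjoint(self, straight_mesh):
        dm = DOFMap(straight_mesh.n_nodes, straight_mesh.n_corners)
        allidx = np.concatenate([dm.field_dofs(f) for f in ("u", "v", "p", "s11", "s12", "s22")])
        assert len(np.unique(allidx)) == dm.n_dofs
        assert allidx.min() == 0 and allidx.max() == dm.n_dofs - 1


class TestMeshIO:
    def test_msh_round_trip_identity(self, stenosis_mesh, tmp_path):
        path = tmp_path / "chan.msh"
        write_mesh(stenosis_mesh, path)
        back = read_msh(path)
        assert np.array_equal(back.coords, stenosis_mesh.coords)
        assert np.array_equal(back.tris, stenosis_mesh.tris)
        assert np.array_equal(back.boundary_edges, stenosis_mesh.boundary_edges)
        assert np.array_equal(back.boundary_tags, stenosis_mesh.boundary_tags)

    def test_two_writes_are_byte_identical(self, straight_mesh, tmp_path):
        p1, p2 = tmp_path / "a.msh", tmp_path / "b.msh"
        write_mesh(straight_mesh, p1)
        write_mesh(straight_mesh, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_vtu_written_and_unsupported_format_rejected(self, straight_mesh, tmp_path):
        write_mesh(straight_mesh, tmp_path / "m.vtu")
        body = (tmp_path / "m.vtu").read_text()
        assert "UnstructuredGrid" in body and "22" in body
        with pytest.raises(ValueError):
            write_mesh(straight_mesh, tmp_path / "m.stl")
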