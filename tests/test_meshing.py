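"""Meshing module: swept and lattice-Delaunay backends, validation,
convergence study, file round-trips."""

import math

import numpy as np
import pytest

from graftflow import geometry as geo
from graftflow import meshing
from graftflow.meshing import MeshQualityError, VolumeMesh


def _cube_surface():
    """Unit cube as a generic (non-parametric) watertight surface."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    tris = np.array([
        [0, 1, 3], [0, 3, 2],          # x=0
        [4, 7, 5], [4, 6, 7],          # x=1
        [0, 5, 1], [0, 4, 5],          # y=0
        [2, 3, 7], [2, 7, 6],          # y=1
        [0, 2, 6], [0, 6, 4],          # z=0
        [1, 5, 7], [1, 7, 3],          # z=1
    ])
    tags = np.full(len(tris), geo.PATCH_WALL)
    tags[10:] = geo.PATCH_OUTLET
    return geo.SurfaceGeometry(v, tris, tags, metadata={"kind": "cube"})


class TestTetrahedralize:
    def test_cube_volume_is_exact(self):
        mesh = meshing.tetrahedralize(_cube_surface(), 0.25)
        assert mesh.tet_volumes().sum() == pytest.approx(1.0, abs=1e-9)

    def test_cylinder_boundary_area(self):
        surf = geo.build_tube_surface(0.15, 1.5, 0.05)
        mesh = meshing.tetrahedralize(surf, 0.05)
        _, areas = mesh.face_normals_areas()
        analytic = 2 * math.pi * 0.15 * 1.5 + 2 * math.pi * 0.15 ** 2
        assert areas.sum() == pytest.approx(analytic, rel=0.03)

    def test_refinement_cardinality_scaling(self):
        surf = geo.build_tube_surface(0.15, 1.0, 0.06)
        coarse = meshing.tetrahedralize(surf, 0.06)
        fine = meshing.tetrahedralize(surf, 0.03)
        ratio = fine.n_tets / coarse.n_tets
        assert 5.0 < ratio < 12.0   # ~(h1/h2)^3 = 8 up to faceting

    def test_median_edge_near_target(self, junction_mesh):
        rep = meshing.validate_mesh(junction_mesh)
        assert rep["median_edge_length"] == pytest.approx(0.06, rel=0.35)

    def test_non_watertight_rejected(self):
        surf = _cube_surface()
        surf.triangles = surf.triangles[:-1]
        surf.patch_tags = surf.patch_tags[:-1]
        with pytest.raises(MeshQualityError, match="watertight"):
            meshing.tetrahedralize(surf, 0.25)

    def test_too_coarse_edge_rejected(self):
        surf = geo.build_tube_surface(0.15, 1.5, 0.05)
        with pytest.raises(ValueError):
            meshing.tetrahedralize(surf, 0.5)


class TestMeshInvariants:
    def test_positive_volumes_and_closure(self, junction_mesh):
        vols = junction_mesh.tet_volumes()
        assert (vols > 0).all()
        normals, areas = junction_mesh.face_normals_areas()
        closure = np.linalg.norm(normals.sum(axis=0)) / areas.sum()
        assert closure < 1e-8

    def test_volume_conservation_junction(self, junction_mesh):
        spec = geo.default_anastomosis_spec()
        surf = geo.build_anastomosis_surface(spec, 0.04)
        # tet volume approaches the (faceted) surface-enclosed volume
        assert junction_mesh.tet_volumes().sum() == pytest.approx(
            surf.enclosed_volume(), rel=0.02)

    def test_boundary_faces_belong_to_one_tet(self, tube_mesh_coarse):
        m = tube_mesh_coarse
        faces = np.sort(np.concatenate([
            m.tets[:, [0, 2, 1]], m.tets[:, [0, 1, 3]],
            m.tets[:, [1, 2, 3]], m.tets[:, [0, 3, 2]]]), axis=1)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        boundary = {tuple(f) for f in np.sort(m.boundary_faces, axis=1)}
        once = {tuple(f) for f in uniq[counts == 1]}
        assert boundary == once

    def test_patch_tags_complete(self, junction_mesh):
        present = set(junction_mesh.boundary_tags)
        assert present == {geo.PATCH_INLET, geo.PATCH_OUTLET,
                           geo.PATCH_WALL, geo.PATCH_CAP}

    def test_stenosed_mesh_watertight_and_smaller(self):
        spec = geo.default_anastomosis_spec()
        plain = meshing.anastomosis_volume_mesh(spec, None, 0.06, seed=0)
        sten = meshing.anastomosis_volume_mesh(
            spec, geo.StenosisSpec(50.0), 0.06, seed=0)
        assert sten.tet_volumes().sum() < plain.tet_volumes().sum()
        normals, areas = sten.face_normals_areas()
        assert np.linalg.norm(normals.sum(axis=0)) / areas.sum() < 1e-8


class TestValidateMesh:
    def test_regular_tet_radius_ratio_is_one(self):
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float)
        mesh = VolumeMesh(v, np.array([[0, 1, 3, 2]]),
                          np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3],
                                    [0, 3, 2]]),
                          np.full(4, geo.PATCH_WALL), 1.0)
        rep = meshing.validate_mesh(mesh)
        assert rep["min_radius_ratio"] == pytest.approx(1.0, rel=1e-12)

    def test_inverted_element_raises(self, tube_mesh_coarse):
        bad = VolumeMesh(tube_mesh_coarse.nodes,
                         tube_mesh_coarse.tets[:, [0, 1, 3, 2]],
                         tube_mesh_coarse.boundary_faces,
                         tube_mesh_coarse.boundary_tags, 0.06)
        with pytest.raises(MeshQualityError, match="inverted"):
            meshing.validate_mesh(bad)

    def test_clean_cylinder_report(self, tube_mesh_coarse):
        rep = meshing.validate_mesh(tube_mesh_coarse)
        assert rep["inverted"] == 0
        assert rep["orphan_nodes"] == 0
        assert rep["min_radius_ratio"] > 0.1


class TestConvergenceStudy:
    def test_tube_approaches_poiseuille(self, fluid):
        surf = geo.build_tube_surface(0.15, 1.5, 0.06)
        rep = meshing.mesh_convergence_study(surf, fluid, 4.0,
                                             [0.075, 0.05], tol=0.2)
        vmaxs = [lvl[3] for lvl in rep.levels]
        # entrance not fully developed in the short tube, but the peak must
        # head toward 2 x mean and grow with refinement
        assert vmaxs[-1] == pytest.approx(8.0, rel=0.15)
        assert rep.relative_errors[0] < 0.2

    def test_identical_levels_converged(self, fluid):
        surf = geo.build_tube_surface(0.15, 1.5, 0.06)
        rep = meshing.mesh_convergence_study(surf, fluid, 4.0,
                                             [0.06, 0.06], tol=0.01)
        assert rep.relative_errors[0] == pytest.approx(0.0, abs=1e-12)
        assert rep.converged_level == 1

    def test_requires_two_levels(self, fluid):
        surf = geo.build_tube_surface(0.15, 1.5, 0.06)
        with pytest.raises(ValueError):
            meshing.mesh_convergence_study(surf, fluid, 4.0, [0.06])


class TestMeshIO:
    @pytest.mark.parametrize("fmt", ["msh", "vtk"])
    def test_round_trip(self, tmp_path, junction_mesh, fmt):
        path = tmp_path / f"mesh.{fmt}"
        meshing.write_mesh(junction_mesh, path)
        back = meshing.read_mesh(path)
        assert back.n_nodes == junction_mesh.n_nodes
        assert np.allclose(back.nodes, junction_mesh.nodes, rtol=0, atol=0)
        assert np.array_equal(np.sort(np.sort(back.tets, axis=1), axis=0),
                              np.sort(np.sort(junction_mesh.tets, axis=1),
                                      axis=0))
        a = {(tuple(sorted(f)), t) for f, t in
             zip(back.boundary_faces, back.boundary_tags)}
        b = {(tuple(sorted(f)), t) for f, t in
             zip(junction_mesh.boundary_faces, junction_mesh.boundary_tags)}
        assert a == b

    def test_cross_format_preserves_connectivity(self, tmp_path,
                                                 tube_mesh_coarse):
        p1 = tmp_path / "m.msh"
        p2 = tmp_path / "m.vtk"
        p3 = tmp_path / "m2.msh"
        meshing.write_mesh(tube_mesh_coarse, p1)
        m1 = meshing.read_mesh(p1)
        meshing.write_mesh(m1, p2)
        m2 = meshing.read_mesh(p2)
        meshing.write_mesh(m2, p3)
        m3 = meshing.read_mesh(p3)
        assert np.array_equal(m2.tets, meshing.read_mesh(p2).tets)
        assert m3.n_tets == tube_mesh_coarse.n_tets
        assert np.allclose(m3.nodes, tube_mesh_coarse.nodes)

    def test_missing_patch_tags_rejected(self, tmp_path, tube_mesh_coarse):
        path = tmp_path / "m.vtk"
        meshing.write_mesh(tube_mesh_coarse, path)
        text = path.read_text().replace("SCALARS patch_tag int 1",
                                        "SCALARS other int 1")
        path.write_text(text)
        from graftflow.mesh_io import MeshFormatError
        with pytest.raises(MeshFormatError, match="patch"):
            meshing.read_mesh(path)

    def test_unsupported_format_rejected(self, tmp_path, tube_mesh_coarse):
        from graftflow.mesh_io import MeshFormatError
        with pytest.raises(MeshFormatError):
            meshing.write_mesh(tube_mesh_coarse, tmp_path / "m.obj")
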