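"""Shared fixtures: small meshes and cheap flow solutions reused across
test modules."""

from __future__ import annotations

import numpy as np
import pytest

from graftflow import geometry as geo
from graftflow import meshing


@pytest.fixture(scope="session")
def fluid():
    return geo.default_fluid()


@pytest.fixture(scope="session")
def tube_surface():
    return geo.build_tube_surface(0.15, 1.5, 0.05)


@pytest.fixture(scope="session")
def anastomosis_surface():
    return geo.build_anastomosis_surface(geo.default_anastomosis_spec(), 0.04)


@pytest.fixture(scope="session")
def tube_mesh_coarse():
    return meshing.tube_volume_mesh(0.15, 1.5, 0.06)


@pytest.fixture(scope="session")
def junction_mesh():
    return meshing.anastomosis_volume_mesh(
        geo.default_anastomosis_spec(), None, 0.06, seed=0)


@pytest.fixture(scope="session")
def box_mesh():
    """Structured tetrahedral unit-box mesh (Couette / flat-strip fixtures).

    Boundary tags: y=0 plane is wall, y=1 is the occluded cap, the four
    remaining sides are inlet/outlet (excluded from wall statistics).
    """
    from scipy.spatial import Delaunay
    from graftflow.meshing import VolumeMesh, _boundary_faces_of, _orient_tets

    n = 8
    ax = np.linspace(0.0, 1.0, n + 1)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"),
                   axis=-1).reshape(-1, 3)
    rng = np.random.default_rng(3)
    interior = np.all((pts > 1e-9) & (pts < 1 - 1e-9), axis=1)
    pts = pts + np.where(interior[:, None],
                         rng.uniform(-0.02, 0.02, pts.shape), 0.0)
    tets = Delaunay(pts).simplices
    x = pts[tets]
    vol = np.abs(np.einsum("ij,ij->i", x[:, 1] - x[:, 0],
                           np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0])))
    tets = _orient_tets(pts, tets[vol > 1e-12])
    faces = _boundary_faces_of(tets)
    fy = pts[faces][:, :, 1]
    tags = np.full(len(faces), geo.PATCH_OUTLET)
    tags[np.all(np.abs(fy) < 1e-9, axis=1)] = geo.PATCH_WALL
    tags[np.all(np.abs(fy - 1.0) < 1e-9, axis=1)] = geo.PATCH_INLET
    return VolumeMesh(pts, tets, faces, tags, 1.0 / n,
                      metadata={"kind": "box"})
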