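"""Linear tetrahedral volume meshes for lumen geometries.

Two built-in mesher backends (the normative contract is the mesh, not the
backend):

* a swept mesher for straight tubes: a structured triangulated disk extruded
  along z, each prism split into three tetrahedra with a globally consistent
  diagonal rule;
* a lattice-Delaunay mesher for the two-cylinder junction: structured section
  rings along host and graft axes, a deterministic interior jitter to break
  lattice degeneracies, scipy Delaunay, and a point-membership filter that
  keeps tetrahedra whose centroid lies inside the lumen union.

Focal stenosis is applied as the same radial warp used for surfaces
(:func:`graftflow.geometry.stenosis_warp`), after meshing the unstenosed
domain, so mesh topology never depends on severity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from graftflow.geometry import (
    PATCH_CAP,
    PATCH_INLET,
    PATCH_OUTLET,
    PATCH_WALL,
    AnastomosisSpec,
    FluidProperties,
    StenosisSpec,
    SurfaceGeometry,
    _disk_triangulation,
    stenosis_unwarp,
    stenosis_warp,
)

__all__ = [
    "VolumeMesh",
    "ConvergenceReport",
    "MeshQualityError",
    "tetrahedralize",
    "tube_volume_mesh",
    "anastomosis_volume_mesh",
    "validate_mesh",
    "mesh_convergence_study",
    "read_mesh",
    "write_mesh",
]


class MeshQualityError(RuntimeError):
    pass


@dataclass
class VolumeMesh:
    """Linear tetrahedral mesh with tagged boundary triangles."""

    nodes: np.ndarray            # (N, 3) float64, cm
    tets: np.ndarray             # (T, 4) int, positively oriented
    boundary_faces: np.ndarray   # (F, 3) int
    boundary_tags: np.ndarray    # (F,) int, legend in geometry.PATCH_NAMES
    edge_length_target: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        return np.einsum("ij,ij->i", x[:, 1] - x[:, 0],
                         np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0])) / 6.0

    def face_normals_areas(self):
        """Outward area-weighted normals of the boundary faces."""
        v = self.nodes
        f = self.boundary_faces
        n = 0.5 * np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return n, np.linalg.norm(n, axis=1)

    def boundary_nodes(self, tag: int | None = None) -> np.ndarray:
        if tag is None:
            return np.unique(self.boundary_faces)
        return np.unique(self.boundary_faces[self.boundary_tags == tag])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _orient_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    x = nodes[tets]
    vol = np.einsum("ij,ij->i", x[:, 1] - x[:, 0],
                    np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]))
    flip = vol < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def _boundary_faces_of(tets: np.ndarray):
    """Faces belonging to exactly one tet, wound so their normal points out
    of the owning tet (hence out of the mesh for positively oriented tets)."""
    # local faces with outward winding for a positively oriented tet
    faces = np.concatenate([tets[:, [0, 2, 1]], tets[:, [0, 1, 3]],
                            tets[:, [1, 2, 3]], tets[:, [0, 3, 2]]])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return faces[counts[inv] == 1]


def _tag_faces(nodes, faces, planes, tol):
    """planes: list of (tag, point, normal); faces with all nodes on a plane
    get that tag, the rest are wall."""
    tags = np.full(len(faces), PATCH_WALL, dtype=int)
    for tag, point, normal in planes:
        point = np.asarray(point, dtype=float)
        normal = np.asarray(normal, dtype=float)
        d = (nodes - point) @ normal
        on = np.abs(d) < tol
        tags[on[faces].all(axis=1)] = tag
    return tags


# ---------------------------------------------------------------------------
# swept tube mesher
# ---------------------------------------------------------------------------

def tube_volume_mesh(radius: float, length: float, edge: float,
                     stenosis: StenosisSpec | None = None,
                     inlet_tag: int = PATCH_INLET) -> VolumeMesh:
    """Structured tube mesh along z: inlet z=0, outlet z=length."""
    n_th = max(12, int(round(2.0 * math.pi * radius / edge)))
    ang = 2.0 * math.pi * np.arange(n_th) / n_th
    ring = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    disk, tris = _disk_triangulation(ring, edge)
    n_d = len(disk)
    n_l = max(2, int(round(length / edge)))
    zs = np.linspace(0.0, length, n_l + 1)

    nodes = np.concatenate([
        np.column_stack([disk, np.full(n_d, z)]) for z in zs])

    tris_sorted = np.sort(tris, axis=1)
    tets = []
    for j in range(n_l):
        lo = j * n_d + tris_sorted
        hi = lo + n_d
        # consistent prism split along sorted global indices
        tets.append(np.column_stack([lo[:, 0], lo[:, 1], lo[:, 2], hi[:, 0]]))
        tets.append(np.column_stack([lo[:, 1], lo[:, 2], hi[:, 0], hi[:, 1]]))
        tets.append(np.column_stack([lo[:, 2], hi[:, 0], hi[:, 1], hi[:, 2]]))
    tets = _orient_tets(nodes, np.concatenate(tets))

    if stenosis is not None and stenosis.area_stenosis_pct > 0:
        nodes = stenosis_warp(nodes, radius, stenosis)
        tets = _orient_tets(nodes, tets)

    faces = _boundary_faces_of(tets)
    tags = _tag_faces(nodes, faces,
                      [(inlet_tag, [0, 0, 0], [0, 0, 1]),
                       (PATCH_OUTLET, [0, 0, length], [0, 0, 1])],
                      tol=1e-9 * max(1.0, length))
    return VolumeMesh(nodes, tets, faces, tags, edge, metadata={
        "kind": "tube", "host_radius": radius, "length": length,
        "z_range": (0.0, length),
        "inlet_plane": {"point": [0.0, 0.0, 0.0], "normal": [0.0, 0.0, -1.0]},
        "outlet_plane": {"point": [0.0, 0.0, length],
                         "normal": [0.0, 0.0, 1.0]},
        "stenosis": stenosis,
    })


# ---------------------------------------------------------------------------
# junction lattice-Delaunay mesher
# ---------------------------------------------------------------------------

def anastomosis_volume_mesh(spec: AnastomosisSpec,
                            stenosis: StenosisSpec | None,
                            edge: float,
                            seed: int = 0) -> VolumeMesh:
    """Mesh the host/graft union by Delaunay of structured section rings."""
    ra, rg = spec.host_radius, spec.graft_radius
    Lp, Ld, Lg = (spec.host_proximal_stub_length, spec.host_distal_length,
                  spec.graft_length)
    a_g, e1, e2 = spec.graft_axis, spec.graft_e1, spec.graft_e2

    # host lattice
    n_th = max(12, int(round(2.0 * math.pi * ra / edge)))
    ang = 2.0 * math.pi * np.arange(n_th) / n_th
    ring = ra * np.column_stack([np.cos(ang), np.sin(ang)])
    disk, _ = _disk_triangulation(ring, edge)
    n_z = max(4, int(round((Lp + Ld) / edge)))
    zs = np.linspace(-Lp, Ld, n_z + 1)

    def _twist(pts2, angle):
        c, s = math.cos(angle), math.sin(angle)
        return pts2 @ np.array([[c, s], [-s, c]])

    # alternate layers are rotated by half the angular pitch (antiprism
    # packing): breaks the cospherical degeneracies of a straight extrusion
    pitch = math.pi / n_th
    host = np.concatenate([
        np.column_stack([_twist(disk, (j % 2) * pitch), np.full(len(disk), z)])
        for j, z in enumerate(zs)])
    host_on_wall = np.tile(np.hypot(disk[:, 0], disk[:, 1]) > ra - 1e-9,
                           len(zs))
    host_on_plane = np.repeat(np.isin(zs, (zs[0], zs[-1])), len(disk))

    # graft lattice (only the part clear of the host cylinder)
    n_tg = max(12, int(round(2.0 * math.pi * rg / edge)))
    angg = 2.0 * math.pi * np.arange(n_tg) / n_tg
    ringg = rg * np.column_stack([np.cos(angg), np.sin(angg)])
    diskg, _ = _disk_triangulation(ringg, edge)
    n_s = max(4, int(round(Lg / edge)))
    ss = np.linspace(0.0, Lg, n_s + 1)
    graft = []
    graft_on_wall = []
    graft_on_plane = []
    pitch_g = math.pi / n_tg
    for k, s in enumerate(ss):
        dg = _twist(diskg, (k % 2) * pitch_g)
        pts = (s * a_g[None, :] + dg[:, 0:1] * e1[None, :]
               + dg[:, 1:2] * e2[None, :])
        rho = np.hypot(pts[:, 0], pts[:, 1])
        keep = rho > ra + 0.35 * edge
        graft.append(pts[keep])
        graft_on_wall.append(
            (np.hypot(diskg[:, 0], diskg[:, 1]) > rg - 1e-9)[keep])
        graft_on_plane.append(np.full(keep.sum(), s == ss[-1]))
    graft = np.concatenate(graft)
    graft_on_wall = np.concatenate(graft_on_wall)
    graft_on_plane = np.concatenate(graft_on_plane)

    # junction seam: the cylinder-cylinder intersection curve
    from graftflow.geometry import _orifice_curve
    n_phi = max(16, int(round(2.0 * math.pi * rg / (0.6 * edge))))
    curve = _orifice_curve(spec, n_phi)

    points = np.concatenate([host, graft, curve])
    on_surface = np.concatenate([
        host_on_wall | host_on_plane, graft_on_wall | graft_on_plane,
        np.ones(len(curve), dtype=bool)])

    # warp the lattice before triangulation: the Delaunay then runs on the
    # stenosed geometry directly and cannot produce tangled elements
    warped = stenosis is not None and stenosis.area_stenosis_pct > 0
    if warped:
        points = stenosis_warp(points, ra, stenosis)

    rng = np.random.default_rng(seed)
    jitter = (0.15 * edge) * rng.uniform(-1.0, 1.0, points.shape)
    jitter[on_surface] = 0.0
    points = points + jitter

    # two Laplacian passes on interior nodes (surface nodes pinned), with a
    # fresh Delaunay after each: relaxes the jittered lattice toward locally
    # centered, well-shaped tets
    interior = ~on_surface
    for _ in range(2):
        tri = Delaunay(points)
        ind, indptr = tri.vertex_neighbor_vertices
        moved = points.copy()
        for v in np.nonzero(interior)[0]:
            nb = indptr[ind[v]:ind[v + 1]]
            if len(nb):
                moved[v] = points[nb].mean(axis=0)
        points = moved

    tri = Delaunay(points)
    tets = tri.simplices
    cent = points[tets].mean(axis=1)

    def inside(q):
        if warped:
            q = stenosis_unwarp(q, ra, stenosis)
        rho = np.hypot(q[:, 0], q[:, 1])
        in_host = (rho <= ra) & (q[:, 2] >= -Lp) & (q[:, 2] <= Ld)
        s = q @ a_g
        d = np.linalg.norm(q - s[:, None] * a_g[None, :], axis=1)
        in_graft = (d <= rg) & (s >= 0.0) & (s <= Lg)
        return in_host | in_graft

    tets = _orient_tets(points, tets[inside(cent)])

    # strip boundary slivers: flat tets whose four nodes all sit on the
    # surface lattice (the interior jitter cannot reach them); their removal
    # moves the discrete boundary by less than the faceting error
    x = points[tets]
    vol = np.abs(np.einsum("ij,ij->i", x[:, 1] - x[:, 0],
                           np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]))) / 6

    def _fa(a, b, c):
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    areas = (_fa(x[:, 0], x[:, 1], x[:, 2]) + _fa(x[:, 0], x[:, 1], x[:, 3])
             + _fa(x[:, 0], x[:, 2], x[:, 3]) + _fa(x[:, 1], x[:, 2], x[:, 3]))
    aspect = 3.0 * vol / areas / edge  # inradius relative to target edge
    n_surf = on_surface[tets].sum(axis=1)
    flat = (aspect < 0.01) & (n_surf >= 3)
    thin = (vol < 0.02 * edge ** 3 / (6.0 * math.sqrt(2.0))) & (n_surf == 4)
    tets = tets[~flat & ~thin & (vol > 1e-9 * edge ** 3)]

    used = np.unique(tets)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = points[used]
    tets = _orient_tets(nodes, remap[tets])

    faces = _boundary_faces_of(tets)
    tol = 1e-6 * max(1.0, Lg + Lp + Ld)
    tags = _tag_faces(nodes, faces,
                      [(PATCH_INLET, Lg * a_g, a_g),
                       (PATCH_OUTLET, [0, 0, Ld], [0, 0, 1]),
                       (PATCH_CAP, [0, 0, -Lp], [0, 0, 1])],
                      tol=tol)
    return VolumeMesh(nodes, tets, faces, tags, edge, metadata={
        "kind": "anastomosis", "spec": spec, "stenosis": stenosis,
        "host_radius": ra, "graft_radius": rg, "seed": seed,
        "z_range": (-Lp, Ld),
        "orifice_curve": curve,
        "inlet_plane": {"point": (Lg * a_g).tolist(), "normal": a_g.tolist()},
        "outlet_plane": {"point": [0.0, 0.0, Ld], "normal": [0.0, 0.0, 1.0]},
        "cap_plane": {"point": [0.0, 0.0, -Lp], "normal": [0.0, 0.0, -1.0]},
        "landmarks": {
            "toe_artery": curve[np.argmax(curve[:, 2])].tolist(),
            "toe_graft": curve[np.argmax(curve[:, 2])].tolist(),
            "heel": curve[np.argmin(curve[:, 2])].tolist(),
            "floor_center": [-ra, 0.0, float(curve[:, 2].mean())],
            "junction_center": [0.0, 0.0, 0.0],
        },
    })


# ---------------------------------------------------------------------------
# generic front end
# ---------------------------------------------------------------------------

def tetrahedralize(surface: SurfaceGeometry, target_edge: float,
                   seed: int = 0) -> VolumeMesh:
    """Volume-mesh a watertight lumen surface.

    Parametric surfaces built by :mod:`graftflow.geometry` dispatch to the
    matching structured backend; anything else falls back to a generic
    lattice + Delaunay + containment filter using trimesh ray casting.
    """
    if not surface.is_watertight():
        raise MeshQualityError(
            "surface is not watertight (open or inconsistently oriented); "
            "cannot tetrahedralize")
    meta = surface.metadata
    host_r = meta.get("host_radius")
    if host_r is not None and target_edge > host_r + 1e-12:
        raise ValueError("target_edge coarser than the host radius")
    kind = meta.get("kind")
    if kind == "tube":
        return tube_volume_mesh(meta["host_radius"], meta["length"],
                                target_edge, stenosis=meta.get("stenosis"))
    if kind == "anastomosis":
        return anastomosis_volume_mesh(meta["spec"], meta.get("stenosis"),
                                       target_edge, seed=seed)
    return _generic_tetrahedralize(surface, target_edge)


def _winding_inside(surface: SurfaceGeometry, pts: np.ndarray,
                    chunk: int = 2048) -> np.ndarray:
    """Generalized winding number containment test (robust for watertight
    oriented surfaces; no spatial index required)."""
    v = surface.vertices
    tris = surface.triangles
    out = np.empty(len(pts), dtype=bool)
    for start in range(0, len(pts), chunk):
        q = pts[start:start + chunk]
        a = v[tris[:, 0]][None, :, :] - q[:, None, :]
        b = v[tris[:, 1]][None, :, :] - q[:, None, :]
        c = v[tris[:, 2]][None, :, :] - q[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("qtj,qtj->qt", a, np.cross(b, c))
        denom = (la * lb * lc + np.einsum("qtj,qtj->qt", a, b) * lc
                 + np.einsum("qtj,qtj->qt", b, c) * la
                 + np.einsum("qtj,qtj->qt", c, a) * lb)
        omega = 2.0 * np.arctan2(det, denom)
        out[start:start + chunk] = omega.sum(axis=1) > 2.0 * np.pi
    return out


def _generic_tetrahedralize(surface: SurfaceGeometry,
                            target_edge: float) -> VolumeMesh:
    lo = surface.vertices.min(axis=0)
    hi = surface.vertices.max(axis=0)
    counts = np.maximum(1, np.round((hi - lo) / target_edge).astype(int))
    axes = [np.linspace(lo[i], hi[i], counts[i] + 1) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # keep strictly interior lattice points, clear of the surface
    dist, _ = cKDTree(surface.vertices).query(grid)
    inside = _winding_inside(surface, grid)
    keep = inside & (dist > 0.3 * target_edge)
    on_face = dist <= 1e-9  # lattice points coincident with surface vertices
    points = np.concatenate([surface.vertices, grid[keep & ~on_face]])
    tets = Delaunay(points).simplices
    cent = points[tets].mean(axis=1)
    tets = tets[_winding_inside(surface, cent)]
    used = np.unique(tets)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = points[used]
    tets = _orient_tets(nodes, remap[tets])
    faces = _boundary_faces_of(tets)
    # inherit tags from the nearest surface triangle
    tri_cent = surface.vertices[surface.triangles].mean(axis=1)
    tree = cKDTree(tri_cent)
    _, nearest = tree.query(nodes[faces].mean(axis=1))
    tags = surface.patch_tags[nearest]
    return VolumeMesh(nodes, tets, faces, tags, target_edge,
                      metadata={"kind": "generic"})


# ---------------------------------------------------------------------------
# validation & convergence
# ---------------------------------------------------------------------------

def validate_mesh(mesh: VolumeMesh) -> dict:
    """Quality report; raises :class:`MeshQualityError` on inverted elements
    or orphan nodes."""
    vols = mesh.tet_volumes()
    inverted = int((vols <= 0).sum())
    if inverted:
        raise MeshQualityError(f"{inverted} inverted tetrahedra")
    x = mesh.nodes[mesh.tets]
    # radius ratio: 3 * inradius / circumradius, 1 for the regular tet
    def _face_area(a, b, c):
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    areas = (_face_area(x[:, 0], x[:, 1], x[:, 2])
             + _face_area(x[:, 0], x[:, 1], x[:, 3])
             + _face_area(x[:, 0], x[:, 2], x[:, 3])
             + _face_area(x[:, 1], x[:, 2], x[:, 3]))
    r_in = 3.0 * vols / areas
    a = np.linalg.norm(x[:, 1] - x[:, 0], axis=1) * \
        np.linalg.norm(x[:, 3] - x[:, 2], axis=1)
    b = np.linalg.norm(x[:, 2] - x[:, 0], axis=1) * \
        np.linalg.norm(x[:, 3] - x[:, 1], axis=1)
    c = np.linalg.norm(x[:, 3] - x[:, 0], axis=1) * \
        np.linalg.norm(x[:, 2] - x[:, 1], axis=1)
    # Crelle / Euler formula for the circumradius
    p = np.sqrt((a + b + c) * (-a + b + c) * (a - b + c) * (a + b - c))
    r_circ = p / (24.0 * vols)
    ratio = 3.0 * r_in / r_circ
    in_tets = np.zeros(mesh.n_nodes, dtype=bool)
    in_tets[np.unique(mesh.tets)] = True
    orphans = int((~in_tets).sum())
    if orphans:
        raise MeshQualityError(f"{orphans} orphan nodes")
    edges = np.concatenate([mesh.tets[:, p] for p in
                            ([0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3])])
    elens = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]],
                           axis=1)
    return {
        "n_nodes": mesh.n_nodes,
        "n_tets": mesh.n_tets,
        "inverted": inverted,
        "orphan_nodes": orphans,
        "min_radius_ratio": float(ratio.min()),
        "median_radius_ratio": float(np.median(ratio)),
        "median_edge_length": float(np.median(elens)),
        "total_volume": float(vols.sum()),
    }


@dataclass
class ConvergenceReport:
    """Mesh-dependency study: steady peak velocity across refinements."""

    levels: list            # (edge_length, n_nodes, n_tets, vmax)
    relative_errors: list   # successive |dv|/v
    converged_level: int | None


def mesh_convergence_study(surface: SurfaceGeometry, props: FluidProperties,
                           inlet_speed: float, edge_lengths,
                           tol: float = 0.01) -> ConvergenceReport:
    """Refine until the steady peak velocity changes by less than ``tol``
    between consecutive levels (inlet at the cycle-mean velocity)."""
    from graftflow.solver import solve_steady

    edge_lengths = sorted(edge_lengths, reverse=True)
    if len(edge_lengths) < 2:
        raise ValueError("need at least two edge lengths")
    levels = []
    for e in edge_lengths:
        mesh = tetrahedralize(surface, e)
        fld = solve_steady(mesh, props, inlet_speed)
        vmax = float(np.linalg.norm(fld.velocity, axis=1).max())
        levels.append((e, mesh.n_nodes, mesh.n_tets, vmax))
    errs = [abs(levels[i + 1][3] - levels[i][3]) / abs(levels[i + 1][3])
            for i in range(len(levels) - 1)]
    converged = next((i + 1 for i, r in enumerate(errs) if r < tol), None)
    return ConvergenceReport(levels, errs, converged)


def read_mesh(path, fmt: str | None = None) -> VolumeMesh:
    from graftflow import mesh_io
    return mesh_io.read_mesh(path, fmt)


def write_mesh(mesh: VolumeMesh, path, fmt: str | None = None) -> None:
    from graftflow import mesh_io
    mesh_io.write_mesh(mesh, path, fmt)
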