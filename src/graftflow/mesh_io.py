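"""Mesh file I/O: Gmsh MSH 4.1 and VTK legacy unstructured grid, ASCII.

Boundary patch tags travel as integer cell data with the fixed legend
{1 inlet, 2 outlet, 3 wall, 4 occluded_cap}.  In MSH files each patch is a
surface entity whose entity tag equals the patch tag; in VTK files boundary
triangles follow the tetrahedra and a ``patch_tag`` CELL_DATA array holds 0
for tets and the patch tag for triangles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from graftflow.meshing import VolumeMesh

__all__ = ["read_mesh", "write_mesh", "write_vtk_fields",
           "write_surface_msh", "MeshFormatError"]

_FMT = "%.17g"


class MeshFormatError(RuntimeError):
    pass


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        f = path.suffix.lstrip(".").lower()
    if f in ("msh", "gmsh"):
        return "msh"
    if f in ("vtk",):
        return "vtk"
    raise MeshFormatError(f"unsupported mesh format {f!r} (use msh or vtk)")


def write_mesh(mesh: VolumeMesh, path, fmt: str | None = None) -> None:
    path = Path(path)
    f = _infer_format(path, fmt)
    if f == "msh":
        _write_msh(mesh, path)
    else:
        _write_vtk(mesh, path)


def read_mesh(path, fmt: str | None = None) -> VolumeMesh:
    path = Path(path)
    f = _infer_format(path, fmt)
    if f == "msh":
        return _read_msh(path)
    return _read_vtk(path)


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1
# ---------------------------------------------------------------------------

def write_surface_msh(surface, path) -> None:
    """Triangulated lumen surface as Gmsh MSH 4.1 (one surface entity per
    patch tag), meshable by external tetrahedralizers."""
    path = Path(path)
    tags_present = sorted(set(int(t) for t in surface.patch_tags))
    lo = surface.vertices.min(axis=0)
    hi = surface.vertices.max(axis=0)
    import numpy as _np
    box = " ".join(_FMT % c for c in _np.concatenate([lo, hi]))
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat", "$Entities",
             f"0 0 {len(tags_present)} 0"]
    for t in tags_present:
        lines.append(f"{t} {box} 0 0")
    lines.append("$EndEntities")
    n = len(surface.vertices)
    lines += ["$Nodes", f"1 {n} 1 {n}", f"2 {tags_present[0]} 0 {n}"]
    lines.extend(str(i + 1) for i in range(n))
    lines.extend(" ".join(_FMT % c for c in p) for p in surface.vertices)
    lines.append("$EndNodes")
    n_tri = len(surface.triangles)
    lines += ["$Elements", f"{len(tags_present)} {n_tri} 1 {n_tri}"]
    eid = 1
    for t in tags_present:
        tris = surface.triangles[surface.patch_tags == t]
        lines.append(f"2 {t} 2 {len(tris)}")
        for tr in tris:
            lines.append(f"{eid} {tr[0] + 1} {tr[1] + 1} {tr[2] + 1}")
            eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _write_msh(mesh: VolumeMesh, path: Path) -> None:
    tags_present = sorted(set(int(t) for t in mesh.boundary_tags))
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    box = " ".join(_FMT % c for c in np.concatenate([lo, hi]))
    lines.append("$Entities")
    lines.append(f"0 0 {len(tags_present)} 1")
    for t in tags_present:
        lines.append(f"{t} {box} 0 0")
    lines.append(f"1 {box} 0 0")
    lines.append("$EndEntities")

    n = mesh.n_nodes
    lines.append("$Nodes")
    lines.append(f"1 {n} 1 {n}")
    lines.append(f"3 1 0 {n}")
    lines.extend(str(i + 1) for i in range(n))
    lines.extend(" ".join(_FMT % c for c in p) for p in mesh.nodes)
    lines.append("$EndNodes")

    n_elem = mesh.n_tets + len(mesh.boundary_faces)
    lines.append("$Elements")
    lines.append(f"{len(tags_present) + 1} {n_elem} 1 {n_elem}")
    eid = 1
    for t in tags_present:
        faces = mesh.boundary_faces[mesh.boundary_tags == t]
        lines.append(f"2 {t} 2 {len(faces)}")
        for fc in faces:
            lines.append(f"{eid} {fc[0] + 1} {fc[1] + 1} {fc[2] + 1}")
            eid += 1
    lines.append(f"3 1 4 {mesh.n_tets}")
    for tet in mesh.tets:
        lines.append(f"{eid} {tet[0] + 1} {tet[1] + 1} "
                     f"{tet[2] + 1} {tet[3] + 1}")
        eid += 1
    lines.append("$EndElements")
    edge = mesh.edge_length_target
    lines.append("$GraftflowMeta")
    lines.append(_FMT % edge)
    lines.append("$EndGraftflowMeta")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> VolumeMesh:
    text = path.read_text().split("\n")
    i = 0

    def seek(section):
        nonlocal i
        while i < len(text) and text[i].strip() != section:
            i += 1
        if i >= len(text):
            raise MeshFormatError(f"missing {section} section")
        i += 1

    seek("$MeshFormat")
    version = text[i].split()[0]
    if not version.startswith("4"):
        raise MeshFormatError(f"unsupported MSH version {version}")
    seek("$Nodes")
    n_blocks, n_nodes = (int(x) for x in text[i].split()[:2])
    i += 1
    coords = np.empty((n_nodes, 3))
    node_ids = np.empty(n_nodes, dtype=int)
    at = 0
    for _ in range(n_blocks):
        nb = int(text[i].split()[3])
        i += 1
        for k in range(nb):
            node_ids[at + k] = int(text[i + k])
        i += nb
        for k in range(nb):
            coords[at + k] = [float(x) for x in text[i + k].split()[:3]]
        i += nb
        at += nb
    order = np.argsort(node_ids)
    coords = coords[order]
    id_map = {int(node_ids[order][k]): k for k in range(n_nodes)}

    seek("$Elements")
    n_blocks = int(text[i].split()[0])
    i += 1
    tets = []
    faces = []
    tags = []
    for _ in range(n_blocks):
        dim, etag, etype, ne = (int(x) for x in text[i].split())
        i += 1
        for k in range(ne):
            parts = [int(x) for x in text[i + k].split()[1:]]
            if etype == 4:
                tets.append([id_map[p] for p in parts])
            elif etype == 2:
                faces.append([id_map[p] for p in parts])
                tags.append(etag)
            else:
                raise MeshFormatError(f"unsupported element type {etype}")
        i += ne
    if not faces:
        raise MeshFormatError("no tagged boundary triangles in MSH file")
    edge = 0.0
    try:
        seek("$GraftflowMeta")
        edge = float(text[i])
    except MeshFormatError:
        pass
    return VolumeMesh(coords, np.asarray(tets, dtype=int),
                      np.asarray(faces, dtype=int),
                      np.asarray(tags, dtype=int), edge)


# ---------------------------------------------------------------------------
# VTK legacy
# ---------------------------------------------------------------------------

def _write_vtk(mesh: VolumeMesh, path: Path,
               point_data: dict | None = None) -> None:
    lines = ["# vtk DataFile Version 3.0", "graftflow mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    lines.extend(" ".join(_FMT % c for c in p) for p in mesh.nodes)
    n_cells = mesh.n_tets + len(mesh.boundary_faces)
    size = 5 * mesh.n_tets + 4 * len(mesh.boundary_faces)
    lines.append(f"CELLS {n_cells} {size}")
    lines.extend("4 " + " ".join(str(v) for v in t) for t in mesh.tets)
    lines.extend("3 " + " ".join(str(v) for v in f)
                 for f in mesh.boundary_faces)
    lines.append(f"CELL_TYPES {n_cells}")
    lines.extend(["10"] * mesh.n_tets)
    lines.extend(["5"] * len(mesh.boundary_faces))
    lines.append(f"CELL_DATA {n_cells}")
    lines.append("SCALARS patch_tag int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(["0"] * mesh.n_tets)
    lines.extend(str(int(t)) for t in mesh.boundary_tags)
    lines.append("FIELD meta 1")
    lines.append("edge_length_target 1 1 double")
    lines.append(_FMT % mesh.edge_length_target)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(_FMT % c for c in row) for row in arr)
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(_FMT % x for x in arr.ravel())
    path.write_text("\n".join(lines) + "\n")


def write_vtk_fields(mesh: VolumeMesh, path, point_data: dict) -> None:
    """VTK snapshot with nodal point-data arrays (velocity, pressure, maps)."""
    _write_vtk(mesh, Path(path), point_data=point_data)


def _read_vtk(path: Path) -> VolumeMesh:
    text = path.read_text().split("\n")
    i = 0
    while not text[i].startswith("POINTS"):
        i += 1
    n = int(text[i].split()[1])
    nodes = np.array([[float(x) for x in text[i + 1 + k].split()]
                      for k in range(n)])
    i += 1 + n
    while not text[i].startswith("CELLS"):
        i += 1
    n_cells = int(text[i].split()[1])
    raw = [text[i + 1 + k].split() for k in range(n_cells)]
    i += 1 + n_cells
    while not text[i].startswith("CELL_TYPES"):
        i += 1
    types = [int(text[i + 1 + k]) for k in range(n_cells)]
    tets = np.array([[int(v) for v in raw[k][1:]]
                     for k in range(n_cells) if types[k] == 10], dtype=int)
    faces = np.array([[int(v) for v in raw[k][1:]]
                      for k in range(n_cells) if types[k] == 5], dtype=int)
    i += 1 + n_cells
    tags = None
    edge = 0.0
    while i < len(text):
        line = text[i]
        if line.startswith("SCALARS patch_tag"):
            vals = []
            j = i + 2
            while len(vals) < n_cells:
                vals.extend(int(x) for x in text[j].split())
                j += 1
            all_tags = np.asarray(vals)
            tags = all_tags[np.asarray(types) == 5]
        if line.startswith("edge_length_target"):
            edge = float(text[i + 1])
        i += 1
    if len(faces) == 0 or tags is None:
        raise MeshFormatError("VTK file lacks boundary patch_tag cell data")
    return VolumeMesh(nodes, tets, faces, tags, edge)
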