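"""Anatomical wall regions and regional statistics.

Regions at the anastomosis follow the standard toe/heel/floor nomenclature:

* Region A -- toe region on the host (coronary) artery wall,
* Region B -- toe region on the graft (vein) wall,
* Region C -- heel region,
* Region D -- host artery wall opposite the junction orifice (the floor).

Each is the set of wall nodes within a geodesic distance
``radius_factor * host_radius`` of its landmark, restricted to its own
vessel's wall.  Axial bands (stenotic/proximal/distal) are one host diameter
wide, centered on the throat and one diameter up/downstream of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.stats import ttest_ind

from graftflow.geometry import PATCH_CAP, PATCH_WALL, AnastomosisSpec
from graftflow.meshing import VolumeMesh
from graftflow.wallshear import WallMaps

__all__ = [
    "Landmarks",
    "RegionMask",
    "RegionStats",
    "TTestResult",
    "locate_landmarks",
    "build_region_masks",
    "region_summary",
    "two_sample_t_test",
]


@dataclass
class Landmarks:
    toe_artery: np.ndarray
    toe_graft: np.ndarray
    heel: np.ndarray
    floor_center: np.ndarray
    junction_center: np.ndarray


@dataclass
class RegionMask:
    label: str
    wall_node_ids: np.ndarray
    surface_area_mm2: float
    node_areas: np.ndarray | None = None   # cm^2, aligned with wall_node_ids


@dataclass
class RegionStats:
    index: str
    mean: float
    sd: float
    n_nodes: int
    area_mm2: float
    area_weighted_mean: float


@dataclass
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool


def locate_landmarks(mesh: VolumeMesh,
                     spec: AnastomosisSpec | None = None) -> Landmarks:
    """Landmarks from mesher metadata, snapped to the nearest wall node."""
    meta = mesh.metadata.get("landmarks")
    if meta is None:
        raise ValueError(
            "mesh carries no junction landmarks (not an anastomosis mesh); "
            "supply them manually")
    wall_ids = np.unique(np.concatenate([
        mesh.boundary_faces[mesh.boundary_tags == PATCH_WALL]]))
    pts = mesh.nodes[wall_ids]

    def snap(p):
        p = np.asarray(p, dtype=float)
        return mesh.nodes[wall_ids[np.argmin(
            np.linalg.norm(pts - p, axis=1))]]

    return Landmarks(
        toe_artery=snap(meta["toe_artery"]),
        toe_graft=snap(meta["toe_graft"]),
        heel=snap(meta["heel"]),
        floor_center=snap(meta["floor_center"]),
        junction_center=np.asarray(meta["junction_center"], dtype=float),
    )


def _wall_graph(mesh: VolumeMesh):
    """Edge graph of the wall (+cap) surface with Euclidean edge lengths."""
    is_wall = np.isin(mesh.boundary_tags, (PATCH_WALL, PATCH_CAP))
    faces = mesh.boundary_faces[is_wall]
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                            faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    w = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]],
                       axis=1)
    n = mesh.n_nodes
    g = sp.coo_matrix((np.concatenate([w, w]),
                       (np.concatenate([edges[:, 0], edges[:, 1]]),
                        np.concatenate([edges[:, 1], edges[:, 0]]))),
                      shape=(n, n)).tocsr()
    return faces, g


def _vessel_of_wall_nodes(mesh: VolumeMesh, spec: AnastomosisSpec):
    """'host' or 'graft' label per node (graft: close to the graft axis and
    beyond the host surface region of the junction)."""
    a_g = spec.graft_axis
    q = mesh.nodes
    s = q @ a_g
    d = np.linalg.norm(q - s[:, None] * a_g[None, :], axis=1)
    rho = np.hypot(q[:, 0], q[:, 1])
    on_graft = (d <= spec.graft_radius * 1.05) & (s > 0) & \
        (rho > spec.host_radius * 0.999)
    return on_graft


def _node_areas(mesh: VolumeMesh, faces: np.ndarray) -> np.ndarray:
    v = mesh.nodes
    n = 0.5 * np.cross(v[faces[:, 1]] - v[faces[:, 0]],
                       v[faces[:, 2]] - v[faces[:, 0]])
    a = np.linalg.norm(n, axis=1)
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, faces.reshape(-1), np.repeat(a, 3) / 3.0)
    return out


def build_region_masks(mesh: VolumeMesh, landmarks: Landmarks,
                       spec: AnastomosisSpec,
                       radius_factor: float = 0.75,
                       throat_z: float | None = None,
                       min_nodes: int = 6) -> dict[str, RegionMask]:
    """Geodesic-disk regions A-D plus the three axial one-diameter bands.

    ``throat_z`` defaults to the junction center (where an anastomotic
    stenosis is centered).  If a disk captures fewer than ``min_nodes``
    wall nodes at the nominal radius (coarse meshes), the radius grows
    geometrically up to twice the host radius before failing; pass
    ``min_nodes=0`` for strict fixed-radius disks."""
    faces, graph = _wall_graph(mesh)
    wall_ids = np.unique(faces)
    node_area = _node_areas(mesh, faces)
    on_graft = _vessel_of_wall_nodes(mesh, spec)
    radius = radius_factor * spec.host_radius
    if throat_z is None:
        throat_z = float(landmarks.junction_center[2])

    def nearest_node(p):
        return wall_ids[np.argmin(np.linalg.norm(
            mesh.nodes[wall_ids] - p, axis=1))]

    def disk(p, restrict=None):
        src = nearest_node(p)
        dist = dijkstra(graph, directed=False, indices=src)
        r = radius
        while True:
            ids = wall_ids[dist[wall_ids] <= r]
            if restrict == "host":
                ids = ids[~on_graft[ids]]
            elif restrict == "graft":
                ids = ids[on_graft[ids]]
            if len(ids) >= max(min_nodes, 3):
                return ids
            if r > 2.0 * spec.host_radius:
                raise ValueError(
                    "empty or degenerate region: geodesic radius too small "
                    "for the mesh resolution")
            r *= 1.25

    def band(center_z):
        d = 2.0 * spec.host_radius
        z = mesh.nodes[:, 2]
        ids = wall_ids[(np.abs(z[wall_ids] - center_z) <= 0.5 * d)
                       & ~on_graft[wall_ids]]
        if len(ids) < 3:
            raise ValueError("empty axial band mask")
        return ids

    d_host = 2.0 * spec.host_radius
    regions = {
        "A": disk(landmarks.toe_artery, restrict="host"),
        "B": disk(landmarks.toe_graft, restrict="graft"),
        "C": disk(landmarks.heel, restrict=None),
        "D": disk(landmarks.floor_center, restrict="host"),
        "stenotic_band": band(throat_z),
        "proximal_band": band(throat_z - d_host),
        "distal_band": band(throat_z + d_host),
    }
    # A and C must be disjoint: resolve overlap toward the closer landmark
    overlap = np.intersect1d(regions["A"], regions["C"])
    if len(overlap):
        d_toe = np.linalg.norm(mesh.nodes[overlap] - landmarks.toe_artery,
                               axis=1)
        d_heel = np.linalg.norm(mesh.nodes[overlap] - landmarks.heel, axis=1)
        to_c = overlap[d_heel < d_toe]
        to_a = overlap[d_heel >= d_toe]
        regions["A"] = np.setdiff1d(regions["A"], to_c)
        regions["C"] = np.setdiff1d(regions["C"], to_a)
    out = {}
    for label, ids in regions.items():
        ids = np.asarray(sorted(ids))
        area = float(node_area[ids].sum()) * 100.0   # cm^2 -> mm^2
        out[label] = RegionMask(label, ids, area, node_area[ids])
    return out


def region_summary(maps: WallMaps, mask: RegionMask, index: str
                   ) -> RegionStats:
    """Node-unweighted mean and sample SD over the mask (area-weighted mean
    recorded alongside)."""
    key = index.lower()
    if key not in ("tawss", "osi", "wssg"):
        raise ValueError(f"unknown index {index!r}")
    values = getattr(maps, key)
    lookup = -np.ones(int(maps.wall_node_ids.max()) + 1, dtype=int)
    lookup[maps.wall_node_ids] = np.arange(len(maps.wall_node_ids))
    idx = lookup[mask.wall_node_ids]
    idx = idx[idx >= 0]
    if len(idx) == 0:
        raise ValueError("mask does not intersect the wall maps")
    vals = values[idx]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    wmean = mean
    if mask.node_areas is not None and len(mask.node_areas) == len(
            mask.wall_node_ids):
        keep = lookup[mask.wall_node_ids] >= 0
        w = mask.node_areas[keep]
        if w.sum() > 0:
            wmean = float((vals * w).sum() / w.sum())
    return RegionStats(index=index.upper(), mean=mean, sd=sd,
                       n_nodes=int(len(vals)), area_mm2=mask.surface_area_mm2,
                       area_weighted_mean=wmean)


def two_sample_t_test(values_a, values_b,
                      equal_var: bool = True) -> TTestResult:
    """Two-sided Student's t test with pooled variance (the spreadsheet
    default); Welch's form behind ``equal_var=False``."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per sample")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if np.allclose(a.mean(), b.mean()):
            return TTestResult(0.0, len(a) + len(b) - 2, 1.0, False)
        raise ValueError("both samples have zero variance")
    res = ttest_ind(a, b, equal_var=equal_var)
    df = (len(a) + len(b) - 2) if equal_var else float(res.df)
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), float(df), p, p < 0.05)
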