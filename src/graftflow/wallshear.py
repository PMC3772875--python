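"""Wall shear vectors and derived hemodynamic indices.

Wall traction is recovered by consistent-flux (variational reaction)
extraction: for each wall node the momentum residual of the discrete
solution, integrated against that node's basis function, equals the boundary
integral of the pseudo-traction; dividing by the lumped boundary mass gives
a nodal traction that is one order more accurate at the wall than raw
element gradients.  The wall shear stress is its projection onto the local
tangent plane (which also removes the pressure part).

Indices over a closed cardiac cycle:

* TAWSS  = (1/T) integral |tau| dt                       (dyne/cm^2)
* OSI    = 0.5 (1 - |integral tau dt| / integral |tau| dt)   in [0, 0.5]
* WSSG   = time average of sqrt((d tau_m/dm)^2 + (d tau_n/dn)^2)
           in a local tangent frame with m along the instantaneous shear
           direction                                      (dyne/cm^3)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from graftflow.geometry import (
    PATCH_CAP,
    PATCH_WALL,
    FluidProperties,
    Waveform,
    waveform_stats,
)
from graftflow.meshing import VolumeMesh
from graftflow.solver import FlowField, FlowSeries

__all__ = [
    "WallShearSeries",
    "WallMaps",
    "DimensionlessSummary",
    "wall_shear_field",
    "wall_shear_series",
    "compute_tawss",
    "compute_osi",
    "compute_wssg",
    "compute_wall_maps",
    "dimensionless_numbers",
    "wall_region_interior_mask",
]


@dataclass
class WallShearSeries:
    """Tangential wall shear vectors per wall node per snapshot."""

    wall_node_ids: np.ndarray   # (W,) node ids into the mesh
    tau: np.ndarray             # (S, W, 3) dyne/cm^2
    times: np.ndarray           # (S,)
    normals: np.ndarray         # (W, 3) outward nodal normals
    mesh: VolumeMesh


@dataclass
class WallMaps:
    """Per-wall-node index maps."""

    wall_node_ids: np.ndarray
    tawss: np.ndarray           # dyne/cm^2
    osi: np.ndarray             # dimensionless in [0, 0.5]
    wssg: np.ndarray            # dyne/cm^3
    interior: np.ndarray        # bool: one-ring clear of patch rims


@dataclass
class DimensionlessSummary:
    re_mean: float
    re_peak: float
    womersley: float


# ---------------------------------------------------------------------------
# traction recovery
# ---------------------------------------------------------------------------

def _wall_topology(mesh: VolumeMesh):
    """Wall(+cap) faces, node ids, outward nodal normals, lumped boundary
    mass, and the interior mask (nodes with no neighbor on another patch)."""
    is_wall = np.isin(mesh.boundary_tags, (PATCH_WALL, PATCH_CAP))
    wall_faces = mesh.boundary_faces[is_wall]
    wall_ids = np.unique(wall_faces)
    normals_f, areas_f = mesh.face_normals_areas()

    acc = np.zeros((mesh.n_nodes, 3))
    np.add.at(acc, wall_faces.reshape(-1),
              np.repeat(normals_f[is_wall], 3, axis=0) / 3.0)
    nrm = np.linalg.norm(acc[wall_ids], axis=1, keepdims=True)
    normals = acc[wall_ids] / np.where(nrm > 0, nrm, 1.0)

    lumped = np.zeros(mesh.n_nodes)
    np.add.at(lumped, mesh.boundary_faces.reshape(-1),
              np.repeat(areas_f, 3) / 3.0)

    other = np.unique(mesh.boundary_faces[~is_wall])
    on_rim = np.isin(wall_ids, other)
    # one-ring buffer: wall nodes sharing a wall face with a rim node
    rim_set = set(wall_ids[on_rim])
    touched = np.zeros(mesh.n_nodes, dtype=bool)
    face_has_rim = np.isin(wall_faces, list(rim_set)).any(axis=1)
    touched[np.unique(wall_faces[face_has_rim])] = True
    interior = ~touched[wall_ids]
    return wall_faces, wall_ids, normals, lumped, interior


def _residual_traction(mesh: VolumeMesh, props: FluidProperties,
                       u: np.ndarray, p: np.ndarray,
                       du_dt: np.ndarray | None) -> np.ndarray:
    """Nodal momentum residual R_k (dyne): boundary pseudo-traction integral
    of the discrete solution against each P1 basis function."""
    nodes, tets = mesh.nodes, mesh.tets
    x = nodes[tets]
    e10, e20, e30 = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]
    vol = np.einsum("ij,ij->i", e10, np.cross(e20, e30)) / 6.0
    J = np.stack([e10, e20, e30], axis=1)
    Jinv = np.linalg.inv(J)
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)

    ue = u[tets]                                   # (E, 4, 3)
    Gu = np.einsum("ekd,eki->eid", g, ue)          # (E, 3, 3) du_i/dx_d
    pe = p[tets].mean(axis=1)                      # (E,)
    a_e = ue.mean(axis=1)                          # element-mean convection

    R = np.zeros((mesh.n_nodes, 3))
    # viscous: mu V (grad u_i . grad phi_k)
    visc = props.mu * vol[:, None, None] * \
        np.einsum("eid,ekd->eki", Gu, g)
    # pressure: -(p, d phi_k/dx_i)
    pres = -(pe * vol)[:, None, None] * g
    contrib = visc + pres
    if props.rho > 0:
        conv = np.einsum("ed,eid->ei", a_e, Gu)    # (E, 3)
        contrib = contrib + (props.rho * vol / 4.0)[:, None, None] \
            * conv[:, None, :]
    np.add.at(R, tets.reshape(-1), contrib.reshape(-1, 3))

    if du_dt is not None and props.rho > 0:
        M = np.full((4, 4), 1.0 / 20.0)
        np.fill_diagonal(M, 1.0 / 10.0)
        dd = du_dt[tets]                            # (E, 4, 3)
        mass = props.rho * vol[:, None, None] * \
            np.einsum("kj,eji->eki", M, dd)
        np.add.at(R, tets.reshape(-1), mass.reshape(-1, 3))
    return R


def wall_shear_field(fld: FlowField, mesh: VolumeMesh,
                     props: FluidProperties,
                     du_dt: np.ndarray | None = None):
    """Tangential wall shear vectors for one snapshot.

    Returns (wall_node_ids, tau (W, 3), normals (W, 3), interior mask)."""
    wall_faces, wall_ids, normals, lumped, interior = _wall_topology(mesh)
    R = _residual_traction(mesh, props, fld.velocity, fld.pressure, du_dt)
    # R integrates the traction exerted ON the fluid; the wall feels the
    # opposite sign
    traction = -R[wall_ids] / lumped[wall_ids][:, None]
    tau = traction - np.einsum("ij,ij->i", traction,
                               normals)[:, None] * normals
    return wall_ids, tau, normals, interior


def wall_shear_series(series: FlowSeries, mesh: VolumeMesh,
                      props: FluidProperties) -> WallShearSeries:
    """Shear vectors over the final cycle; the time-derivative term of the
    momentum residual uses the backward difference of consecutive snapshots
    (periodic wrap at the cycle start)."""
    S = series.n_snapshots
    dt = series.settings.dt
    wall_faces, wall_ids, normals, lumped, interior = _wall_topology(mesh)
    taus = np.empty((S, len(wall_ids), 3))
    for s in range(S):
        u = series.velocity[s]
        # snapshot 0 and snapshot S-1 share the cycle phase; the step before
        # snapshot 0 is, by periodicity, snapshot S-2
        u_prev = series.velocity[s - 1] if s > 0 else series.velocity[S - 2]
        du_dt = (u - u_prev) / dt
        R = _residual_traction(mesh, props, u, series.pressure[s], du_dt)
        traction = -R[wall_ids] / lumped[wall_ids][:, None]
        taus[s] = traction - np.einsum(
            "ij,ij->i", traction, normals)[:, None] * normals
    return WallShearSeries(wall_ids, taus, series.times.copy(), normals,
                           mesh)


# ---------------------------------------------------------------------------
# cycle indices
# ---------------------------------------------------------------------------

def _cycle_trapz(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """(1/T) integral over the closed cycle (first axis)."""
    T = times[-1] - times[0]
    return np.trapezoid(values, times, axis=0) / T


def compute_tawss(ws: WallShearSeries) -> np.ndarray:
    """Time-averaged wall shear stress magnitude (dyne/cm^2)."""
    mag = np.linalg.norm(ws.tau, axis=2)
    return _cycle_trapz(mag, ws.times)


def compute_osi(ws: WallShearSeries) -> np.ndarray:
    """Oscillatory shear index in [0, 0.5]; 0 where the shear vanishes."""
    mean_vec = _cycle_trapz(ws.tau, ws.times)
    mean_mag = _cycle_trapz(np.linalg.norm(ws.tau, axis=2), ws.times)
    num = np.linalg.norm(mean_vec, axis=1)
    osi = np.where(mean_mag > 0,
                   0.5 * (1.0 - num / np.where(mean_mag > 0, mean_mag, 1.0)),
                   0.0)
    return np.clip(osi, 0.0, 0.5)


def _wall_triangles(ws: WallShearSeries):
    mesh = ws.mesh
    is_wall = np.isin(mesh.boundary_tags, (PATCH_WALL, PATCH_CAP))
    faces = mesh.boundary_faces[is_wall]
    remap = -np.ones(mesh.n_nodes, dtype=int)
    remap[ws.wall_node_ids] = np.arange(len(ws.wall_node_ids))
    return remap[faces]                     # indices into wall arrays


def compute_wssg(ws: WallShearSeries, mesh: VolumeMesh | None = None
                 ) -> np.ndarray:
    """Time-averaged surface gradient magnitude of the shear field
    (dyne/cm^3) in the instantaneous (m, n) tangent frame."""
    mesh = mesh or ws.mesh
    faces = _wall_triangles(ws)
    pts = mesh.nodes[ws.wall_node_ids]
    p0, p1, p2 = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
    e1 = p1 - p0
    e2 = p2 - p0
    nf = np.cross(e1, e2)
    area2 = np.linalg.norm(nf, axis=1)
    ok = area2 > 0
    nf_hat = nf / np.where(area2 > 0, area2, 1.0)[:, None]
    # P1 surface gradient operator: grad f = sum_k f_k c_k with
    # c_0 = (n x (p2 - p1)) / (2A) etc.
    inv2A = 1.0 / np.where(area2 > 0, area2, 1.0)
    c0 = np.cross(nf_hat, p2 - p1) * inv2A[:, None]
    c1 = np.cross(nf_hat, p0 - p2) * inv2A[:, None]
    c2 = np.cross(nf_hat, p1 - p0) * inv2A[:, None]

    mean_tau = _cycle_trapz(ws.tau, ws.times)       # fallback direction
    fallback = mean_tau[faces].mean(axis=1)
    area_f = 0.5 * area2

    S = len(ws.times)
    acc = np.zeros((S, len(faces)))
    for s in range(S):
        tf = ws.tau[s][faces]                       # (F, 3, 3)
        m = tf.mean(axis=1)
        weak = np.linalg.norm(m, axis=1) < 1e-12
        m[weak] = fallback[weak]
        mn = np.linalg.norm(m, axis=1)
        m = m / np.where(mn > 0, mn, 1.0)[:, None]
        # project m into the face plane
        m = m - np.einsum("ij,ij->i", m, nf_hat)[:, None] * nf_hat
        mn = np.linalg.norm(m, axis=1)
        m = m / np.where(mn > 1e-12, mn, 1.0)[:, None]
        n_t = np.cross(nf_hat, m)
        f_m = np.einsum("fkj,fj->fk", tf, m)        # tau . m at vertices
        f_n = np.einsum("fkj,fj->fk", tf, n_t)
        grad_m = (f_m[:, 0:1] * c0 + f_m[:, 1:2] * c1 + f_m[:, 2:3] * c2)
        grad_n = (f_n[:, 0:1] * c0 + f_n[:, 1:2] * c1 + f_n[:, 2:3] * c2)
        dmm = np.einsum("fj,fj->f", grad_m, m)
        dnn = np.einsum("fj,fj->f", grad_n, n_t)
        acc[s] = np.sqrt(dmm ** 2 + dnn ** 2)

    wssg_face_t = _cycle_trapz(acc, ws.times)       # (F,)
    # area-weight faces to nodes
    num = np.zeros(len(ws.wall_node_ids))
    den = np.zeros(len(ws.wall_node_ids))
    w = (area_f * wssg_face_t)
    for k in range(3):
        np.add.at(num, faces[:, k], w)
        np.add.at(den, faces[:, k], area_f)
    return num / np.where(den > 0, den, 1.0)


def compute_wall_maps(series: FlowSeries, mesh: VolumeMesh,
                      props: FluidProperties) -> WallMaps:
    ws = wall_shear_series(series, mesh, props)
    _, _, _, _, interior = _wall_topology(mesh)
    return WallMaps(ws.wall_node_ids, compute_tawss(ws), compute_osi(ws),
                    compute_wssg(ws), interior)


def wall_region_interior_mask(mesh: VolumeMesh) -> np.ndarray:
    """Wall nodes whose one-ring stays clear of inlet/outlet rims."""
    _, wall_ids, _, _, interior = _wall_topology(mesh)
    return wall_ids[interior]


def dimensionless_numbers(w: Waveform, graft_diameter: float,
                          props: FluidProperties) -> DimensionlessSummary:
    """Inlet Reynolds numbers (cycle-mean and peak velocity) and the
    Womersley number alpha = (d/2) sqrt(2 pi rho / (T mu))."""
    if graft_diameter <= 0:
        raise ValueError("graft_diameter must be positive")
    st = waveform_stats(w)
    re_mean = props.rho * st["mean"] * graft_diameter / props.mu
    re_peak = props.rho * st["peak"] * graft_diameter / props.mu
    alpha = 0.5 * graft_diameter * np.sqrt(
        2.0 * np.pi * props.rho / (w.period * props.mu))
    return DimensionlessSummary(float(re_mean), float(re_peak), float(alpha))
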