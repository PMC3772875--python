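"""Parametric end-to-side anastomosis lumens and pulsatile inlet waveforms.

All quantities are CGS (cm, s, g, dyne, Poise). The host (coronary) artery is a
straight cylinder along the z axis with the junction at the origin; the graft
(vein) is a straight cylinder whose centerline meets the host centerline at the
graft angle theta, approaching from the +x half-space so that graft inflow is
directed distally (toward +z, the host outlet).

Focal stenosis is modelled as a smooth radial warp of space: a cosine taper in
the axial coordinate scales radii so that the throat cross-sectional area is
reduced by exactly the requested percentage, with the displacement fading out
radially beyond the host radius.  The same warp is applied to surface vertices
here and to volume-mesh nodes in :mod:`graftflow.meshing`, so surface and
volume stay consistent.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import Delaunay

__all__ = [
    "FluidProperties",
    "AnastomosisSpec",
    "StenosisSpec",
    "SurfaceGeometry",
    "Waveform",
    "PATCH_INLET",
    "PATCH_OUTLET",
    "PATCH_WALL",
    "PATCH_CAP",
    "PATCH_NAMES",
    "build_anastomosis_surface",
    "build_tube_surface",
    "apply_stenosis",
    "measure_area_stenosis",
    "classify_stenosis",
    "synthesize_inlet_waveform",
    "waveform_stats",
    "default_fluid",
    "default_anastomosis_spec",
    "default_waveform",
    "write_stl",
    "write_waveform_csv",
]

# Patch tag legend, shared with the mesh file formats (integer cell data).
PATCH_INLET = 1
PATCH_OUTLET = 2
PATCH_WALL = 3
PATCH_CAP = 4
PATCH_NAMES = {PATCH_INLET: "inlet", PATCH_OUTLET: "outlet",
               PATCH_WALL: "wall", PATCH_CAP: "occluded_cap"}


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood analogue: dynamic viscosity (Poise), density (g/cm^3)."""

    mu: float = 0.04
    rho: float = 1.06

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"viscosity must be positive, got {self.mu}")
        if self.rho < 0:
            raise ValueError(f"density must be non-negative, got {self.rho}")

    @property
    def nu(self) -> float:
        """Kinematic viscosity (cm^2/s)."""
        return self.mu / self.rho


def default_fluid() -> FluidProperties:
    """Blood at ~45% hematocrit: 4.0 cp, 1.06 g/cm^3."""
    return FluidProperties(mu=0.04, rho=1.06)


@dataclass(frozen=True)
class AnastomosisSpec:
    """Geometry of a straight host artery with an end-to-side graft.

    Parameters
    ----------
    host_radius
        Host (coronary) lumen radius in cm.
    csa_ratio
        Graft-to-host cross-sectional area ratio A_g / A_a; the graft radius
        is ``host_radius * sqrt(csa_ratio)``.
    graft_angle_deg
        Angle theta between graft and host centerlines, degrees, in (0, 90].
    graft_length
        Graft centerline length from the junction center to the inlet plane.
    host_distal_length
        Host length from the junction center to the outlet plane.
    host_proximal_stub_length
        Length of the occluded proximal host stub (capped, no-slip).
    """

    host_radius: float = 0.15
    csa_ratio: float = 1.0
    graft_angle_deg: float = 45.0
    graft_length: float = 0.7
    host_distal_length: float = 0.9
    host_proximal_stub_length: float = 0.6

    def __post_init__(self) -> None:
        if self.host_radius <= 0:
            raise ValueError("host_radius must be positive")
        if self.csa_ratio <= 0:
            raise ValueError("csa_ratio must be positive")
        if not 0.0 < self.graft_angle_deg <= 90.0:
            raise ValueError("graft_angle_deg must lie in (0, 90]")
        d = 2.0 * self.host_radius
        if self.graft_length < 2.0 * d or self.host_distal_length < 2.0 * d:
            raise ValueError(
                "graft_length and host_distal_length must be at least two "
                "host diameters for flow development")
        if self.host_proximal_stub_length <= 0:
            raise ValueError("host_proximal_stub_length must be positive")

    @property
    def graft_radius(self) -> float:
        return self.host_radius * math.sqrt(self.csa_ratio)

    @property
    def graft_axis(self) -> np.ndarray:
        """Unit vector from junction center toward the graft inlet."""
        th = math.radians(self.graft_angle_deg)
        return np.array([math.sin(th), 0.0, -math.cos(th)])

    @property
    def graft_e1(self) -> np.ndarray:
        """In-plane unit vector normal to the graft axis (x-z plane)."""
        th = math.radians(self.graft_angle_deg)
        return np.array([math.cos(th), 0.0, math.sin(th)])

    @property
    def graft_e2(self) -> np.ndarray:
        return np.array([0.0, 1.0, 0.0])


def default_anastomosis_spec() -> AnastomosisSpec:
    """Idealized reference case: 0.30 cm host, CSA ratio 1, theta 45 deg."""
    return AnastomosisSpec()


@dataclass(frozen=True)
class StenosisSpec:
    """Focal area stenosis on the host conduit.

    ``axial_center`` is measured along the host axis from the junction center;
    ``axial_extent`` is the band half-length; the taper removes
    ``area_stenosis_pct`` percent of the reference (unstenosed distal host)
    cross-sectional area at the throat.
    """

    area_stenosis_pct: float
    axial_center: float = 0.0
    axial_extent: float = 0.45   # 1.5 default host diameters (half-length)
    profile: str = "cosine"

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_stenosis_pct < 100.0:
            raise ValueError("area_stenosis_pct must lie in [0, 100)")
        if self.axial_extent <= 0:
            raise ValueError("axial_extent must be positive")
        if self.profile != "cosine":
            raise ValueError(f"unknown stenosis profile {self.profile!r}")


@dataclass
class SurfaceGeometry:
    """Watertight triangulated lumen surface with tagged boundary patches."""

    vertices: np.ndarray          # (N, 3) float64, cm
    triangles: np.ndarray         # (M, 3) int
    patch_tags: np.ndarray        # (M,) int, legend in PATCH_NAMES
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "SurfaceGeometry":
        return SurfaceGeometry(self.vertices.copy(), self.triangles.copy(),
                               self.patch_tags.copy(), dict(self.metadata))

    # -- queries -----------------------------------------------------------
    def triangle_normals(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return n  # unnormalized (2x area vector)

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_normals(), axis=1)

    def patch_area(self, tag: int) -> float:
        return float(self.triangle_areas()[self.patch_tags == tag].sum())

    def is_watertight(self) -> bool:
        """Every directed edge appears exactly once (closed + consistently
        oriented)."""
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        fwd = set(map(tuple, edges))
        if len(fwd) != len(edges):
            return False
        return all((b, a) in fwd for a, b in fwd)

    def enclosed_volume(self) -> float:
        """Volume by divergence theorem (requires outward orientation)."""
        v = self.vertices
        t = self.triangles
        return float(np.einsum(
            "ij,ij->i", v[t[:, 0]],
            np.cross(v[t[:, 1]], v[t[:, 2]])).sum() / 6.0)


# ---------------------------------------------------------------------------
# Inlet waveform
# ---------------------------------------------------------------------------

@dataclass
class Waveform:
    """Periodic cross-section-mean inlet velocity signal (cm/s)."""

    period: float
    sample_times: np.ndarray
    sample_velocities: np.ndarray
    mean_velocity: float
    fourier: dict | None = None  # {"amplitudes": [...], "phases": [...]}

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        v = np.asarray(self.sample_velocities, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("sample_times and sample_velocities must be "
                             "1-D arrays of equal length")
        dt = np.diff(t)
        if t[0] != 0.0 or not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise ValueError("samples must be uniform over [0, T)")
        if np.any(v < 0):
            raise ValueError("inlet velocity must be non-negative "
                             "(unidirectional graft inflow)")
        if abs(v.mean() - self.mean_velocity) > 1e-10 * abs(self.mean_velocity):
            raise ValueError("sample mean disagrees with mean_velocity")
        self.sample_times = t
        self.sample_velocities = v

    def velocity_at(self, t) -> np.ndarray | float:
        """Periodic evaluation; exact when Fourier coefficients are known."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        if self.fourier is not None:
            a = np.asarray(self.fourier["amplitudes"], dtype=float)
            ph = np.asarray(self.fourier["phases"], dtype=float)
            k = np.arange(1, len(a) + 1)
            arg = 2.0 * np.pi * np.outer(tt, k) / self.period + ph
            out = self.mean_velocity * (1.0 + (np.cos(arg) * a).sum(axis=-1))
            return out.reshape(np.shape(t)) if np.ndim(t) else float(out[0])
        tp = np.append(self.sample_times, self.period)
        vp = np.append(self.sample_velocities, self.sample_velocities[0])
        out = np.interp(tt, tp, vp)
        return out if np.ndim(t) else float(out)


def synthesize_inlet_waveform(mean_velocity: float = 12.0,
                              period: float = 0.84095,
                              harmonic_amplitudes=(0.8, 0.35),
                              harmonic_phases=(math.pi, math.pi / 2),
                              n_samples: int = 121) -> Waveform:
    """Non-negative pulsatile inlet wave v(t) = V (1 + sum a_k cos(2 pi k t/T + phi_k)).

    The defaults emulate a saphenous-vein-graft velocity wave: strongly
    pulsatile (peak/mean ~ 2) but never reversing.  The default period is
    121 x 0.00695 s so one cardiac cycle divides into the reference number
    of solver steps exactly.
    """
    if n_samples < 32:
        raise ValueError("n_samples must be at least 32")
    if len(harmonic_amplitudes) != len(harmonic_phases):
        raise ValueError("amplitudes and phases must have equal length")
    if mean_velocity <= 0 or period <= 0:
        raise ValueError("mean_velocity and period must be positive")
    a = np.asarray(harmonic_amplitudes, dtype=float)
    ph = np.asarray(harmonic_phases, dtype=float)
    k = np.arange(1, len(a) + 1)

    def evaluate(t):
        arg = 2.0 * np.pi * np.outer(t, k) / period + ph
        return mean_velocity * (1.0 + (np.cos(arg) * a).sum(axis=1))

    dense = evaluate(np.linspace(0.0, period, 4096, endpoint=False))
    if dense.min() < 0.0:
        raise ValueError(
            f"harmonics drive the inlet velocity negative "
            f"(min {dense.min():.4g} cm/s); reduce amplitudes")
    times = np.arange(n_samples) * (period / n_samples)
    values = evaluate(times)
    # uniform sampling of a pure harmonic sums to zero, so the sample mean is
    # the Fourier mean up to roundoff; nudge it exact for the invariant
    values = np.maximum(values - (values.mean() - mean_velocity), 0.0)
    return Waveform(period=period, sample_times=times,
                    sample_velocities=values, mean_velocity=mean_velocity,
                    fourier={"amplitudes": list(a), "phases": list(ph)})


def default_waveform(n_samples: int = 121) -> Waveform:
    return synthesize_inlet_waveform(n_samples=n_samples)


def waveform_stats(w: Waveform) -> dict:
    """Cycle mean (trapezoid over the closed cycle), peak and peak/mean."""
    vp = np.append(w.sample_velocities, w.sample_velocities[0])
    tp = np.append(w.sample_times, w.period)
    mean = float(np.trapezoid(vp, tp) / w.period)
    peak = float(w.sample_velocities.max())
    return {"mean": mean, "peak": peak, "peak_to_mean": peak / mean}


# ---------------------------------------------------------------------------
# Surface construction helpers
# ---------------------------------------------------------------------------

def _disk_triangulation(boundary_xy: np.ndarray, target_edge: float):
    """Triangulate a planar disk whose boundary polyline is given in order.

    Returns (points_xy, triangles) where the first ``len(boundary_xy)`` points
    are the boundary vertices in input order and triangles are ccw.
    """
    nb = len(boundary_xy)
    center = boundary_xy.mean(axis=0)
    radius = np.linalg.norm(boundary_xy - center, axis=1).mean()
    m = max(1, int(round(radius / target_edge)))
    pts = [boundary_xy]
    for i in range(m - 1, 0, -1):
        r_i = radius * i / m
        n_i = max(6, int(round(nb * i / m)))
        ang = 2.0 * np.pi * (np.arange(n_i) + 0.5 * (m - i)) / n_i
        pts.append(center + r_i * np.column_stack([np.cos(ang), np.sin(ang)]))
    pts.append(center[None, :])
    pts = np.concatenate(pts)
    tri = Delaunay(pts)
    simp = tri.simplices
    # enforce ccw
    u = pts[simp[:, 1]] - pts[simp[:, 0]]
    v = pts[simp[:, 2]] - pts[simp[:, 0]]
    d = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    simp[d < 0] = simp[d < 0][:, [0, 2, 1]]
    return pts, simp


def _weld(vertices: np.ndarray, triangles: np.ndarray, tol: float = 1e-8):
    """Merge duplicate vertices (rounded to tol) and drop degenerate tris."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    verts = vertices[first]
    tris = inverse[triangles]
    ok = ((tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2])
          & (tris[:, 0] != tris[:, 2]))
    return verts, tris, ok


def build_tube_surface(radius: float, length: float, resolution: float,
                       with_inlet_cap: bool = True) -> SurfaceGeometry:
    """Straight cylinder along z: inlet plane z=0, outlet plane z=length.

    Serves as the validation geometry (Poiseuille / Womersley / stenosed-tube
    fixtures).  ``with_inlet_cap=False`` leaves the upstream end tagged as an
    occluded cap instead of an inlet (occluded-stub fixture).
    """
    if resolution > radius / 2.0 + 1e-12:
        raise ValueError("resolution coarser than half the radius")
    n_th = max(12, int(round(2.0 * np.pi * radius / resolution)))
    n_z = max(2, int(round(length / resolution)))
    theta = 2.0 * np.pi * np.arange(n_th) / n_th
    zs = np.linspace(0.0, length, n_z + 1)
    ring = radius * np.column_stack([np.cos(theta), np.sin(theta)])

    verts = []
    tris = []
    tags = []
    for z in zs:
        verts.append(np.column_stack([ring, np.full(n_th, z)]))
    verts = np.concatenate(verts)

    def vid(j, i):
        return j * n_th + (i % n_th)

    for j in range(n_z):
        for i in range(n_th):
            a, b = vid(j, i), vid(j, i + 1)
            c, d = vid(j + 1, i), vid(j + 1, i + 1)
            # outward orientation (radial)
            tris.append([a, b, d])
            tris.append([a, d, c])
            tags += [PATCH_WALL, PATCH_WALL]

    base = len(verts)
    cap_pts, cap_tris = _disk_triangulation(ring, resolution)
    # inlet cap at z=0: outward normal is -z, so flip ccw (in xy) triangles
    inlet_v = np.column_stack([cap_pts, np.zeros(len(cap_pts))])
    inlet_t = base + cap_tris[:, [0, 2, 1]]
    inlet_tag = PATCH_INLET if with_inlet_cap else PATCH_CAP
    base2 = base + len(cap_pts)
    outlet_v = np.column_stack([cap_pts, np.full(len(cap_pts), length)])
    outlet_t = base2 + cap_tris

    verts = np.concatenate([verts, inlet_v, outlet_v])
    tris = np.concatenate([np.asarray(tris), inlet_t, outlet_t])
    tags = np.concatenate([np.asarray(tags),
                           np.full(len(cap_tris), inlet_tag),
                           np.full(len(cap_tris), PATCH_OUTLET)])
    verts, tris, ok = _weld(verts, tris)
    surf = SurfaceGeometry(verts, tris[ok], tags[ok], metadata={
        "kind": "tube",
        "host_radius": radius,
        "length": length,
        "resolution": resolution,
        "z_range": (0.0, length),
        "inlet_plane": {"point": [0.0, 0.0, 0.0], "normal": [0.0, 0.0, -1.0]},
        "outlet_plane": {"point": [0.0, 0.0, length],
                         "normal": [0.0, 0.0, 1.0]},
    })
    return surf


def _orifice_curve(spec: AnastomosisSpec, n_phi: int) -> np.ndarray:
    """Intersection curve of graft and host cylinders, sampled at n_phi
    azimuths of the graft section (phi=0 at the toe side)."""
    ra, rg = spec.host_radius, spec.graft_radius
    th = math.radians(spec.graft_angle_deg)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    b = rg * np.cos(phi) * math.cos(th)
    c = rg * np.sin(phi)
    disc = ra * ra - c * c
    if np.any(disc < -1e-12 * ra * ra):
        raise ValueError("graft wider than host: orifice curve undefined")
    s = (np.sqrt(np.maximum(disc, 0.0)) - b) / math.sin(th)
    pts = (s[:, None] * spec.graft_axis[None, :]
           + rg * np.cos(phi)[:, None] * spec.graft_e1[None, :]
           + rg * np.sin(phi)[:, None] * spec.graft_e2[None, :])
    if np.any(s >= spec.graft_length):
        raise ValueError("graft too short: junction reaches the inlet plane "
                         "(self-intersecting configuration)")
    return pts


def build_anastomosis_surface(spec: AnastomosisSpec,
                              resolution: float) -> SurfaceGeometry:
    """Watertight union of host and graft cylinders with tagged patches.

    The junction orifice is the trimmed cylinder-cylinder intersection curve;
    toe/heel/floor landmark coordinates are recorded in the metadata.
    """
    ra, rg = spec.host_radius, spec.graft_radius
    if resolution > ra / 2.0 + 1e-12:
        raise ValueError("resolution coarser than half the host radius")
    Lp = spec.host_proximal_stub_length
    Ld = spec.host_distal_length
    Lg = spec.graft_length
    a_g, e1, e2 = spec.graft_axis, spec.graft_e1, spec.graft_e2

    # orifice curve, sampled finely enough in the host parameter plane
    n_phi = max(16, int(round(2.0 * np.pi * rg / (0.75 * resolution))))
    n_phi += n_phi % 2  # even: keeps the y-mirror symmetry of the sampling
    curve = _orifice_curve(spec, n_phi)

    def graft_s_d(q):
        """Axial coordinate along and radial distance from the graft axis."""
        s = q @ a_g
        w = q - np.outer(s, a_g)
        return s, np.linalg.norm(w, axis=1)

    # ---- host wall: (theta, z) grid minus the orifice hole ---------------
    n_th = max(16, int(round(2.0 * np.pi * ra / resolution)))
    n_th += n_th % 2
    n_z = max(4, int(round((Lp + Ld) / resolution)))
    thetas = np.linspace(-np.pi, np.pi, n_th + 1)
    zs = np.linspace(-Lp, Ld, n_z + 1)
    TH, ZZ = np.meshgrid(thetas, zs, indexing="ij")
    grid2 = np.column_stack([ra * TH.ravel(), ZZ.ravel()])
    grid3 = np.column_stack([ra * np.cos(TH.ravel()), ra * np.sin(TH.ravel()),
                             ZZ.ravel()])
    s_g, d_g = graft_s_d(grid3)
    near_hole = (d_g < rg + 0.45 * resolution) & (grid3[:, 0] > 0)
    keep = ~near_hole
    curve2 = np.column_stack([ra * np.arctan2(curve[:, 1], curve[:, 0]),
                              curve[:, 2]])
    host2 = np.concatenate([grid2[keep], curve2])
    host3 = np.concatenate([grid3[keep], curve])
    tri2 = Delaunay(host2)
    simp = tri2.simplices
    # drop triangles inside the orifice (point-in-polygon in parameter space)
    cent2 = host2[simp].mean(axis=1)
    hole = MplPath(curve2, closed=True)
    inside = hole.contains_points(cent2, radius=1e-12)
    # also drop parameter-space slivers along the hole rim
    p0, p1, p2 = host2[simp[:, 0]], host2[simp[:, 1]], host2[simp[:, 2]]
    u12, v12 = p1 - p0, p2 - p0
    area2 = 0.5 * (u12[:, 0] * v12[:, 1] - u12[:, 1] * v12[:, 0])
    good = (~inside) & (np.abs(area2) > 1e-6 * resolution ** 2)
    simp = simp[good]
    area2 = area2[good]
    simp[area2 < 0] = simp[area2 < 0][:, [0, 2, 1]]  # ccw -> outward radial

    verts = [host3]
    tris = [simp]
    tags = [np.full(len(simp), PATCH_WALL)]
    offset = len(host3)
    curve_idx0 = len(grid3[keep])  # curve vertices within host3

    # ---- graft wall: rings from the orifice curve to the inlet plane -----
    s_curve = curve @ a_g
    span = float(np.mean(Lg - s_curve))
    n_k = max(3, int(round(span / resolution)))
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    sec = (np.cos(phi)[:, None] * e1[None, :]
           + np.sin(phi)[:, None] * e2[None, :])
    graft_rings = []
    for k in range(1, n_k + 1):
        s_k = s_curve + (k / n_k) * (Lg - s_curve)
        graft_rings.append(s_k[:, None] * a_g[None, :] + rg * sec)
    graft_v = np.concatenate(graft_rings)
    g_tris = []
    for k in range(n_k):
        if k == 0:
            lower = curve_idx0 + np.arange(n_phi)          # in host3 block
        else:
            lower = offset + (k - 1) * n_phi + np.arange(n_phi)
        upper = offset + k * n_phi + np.arange(n_phi)
        for i in range(n_phi):
            a, b = lower[i], lower[(i + 1) % n_phi]
            c, d = upper[i], upper[(i + 1) % n_phi]
            # (e1, e2, a_g) is left-handed (e1 x e2 = -a_g), so walking +phi
            # then +s must wind (a, d, b) / (a, c, d) for outward normals
            g_tris.append([a, d, b])
            g_tris.append([a, c, d])
    verts.append(graft_v)
    tris.append(np.asarray(g_tris))
    tags.append(np.full(len(g_tris), PATCH_WALL))
    offset += len(graft_v)

    # ---- inlet cap (graft free end) --------------------------------------
    ring2 = rg * np.column_stack([np.cos(phi), np.sin(phi)])
    cap_pts, cap_tris = _disk_triangulation(ring2, resolution)
    inlet_v = (Lg * a_g[None, :]
               + cap_pts[:, 0:1] * e1[None, :] + cap_pts[:, 1:2] * e2[None, :])
    # ccw in (e1, e2) maps to -a_g normals (left-handed triple): flip for the
    # outward +a_g direction
    verts.append(inlet_v)
    tris.append(offset + cap_tris[:, [0, 2, 1]])
    tags.append(np.full(len(cap_tris), PATCH_INLET))
    offset += len(inlet_v)

    # ---- host end caps ----------------------------------------------------
    host_ring = ra * np.column_stack([np.cos(thetas[:-1]), np.sin(thetas[:-1])])
    dk_pts, dk_tris = _disk_triangulation(host_ring, resolution)
    outlet_v = np.column_stack([dk_pts, np.full(len(dk_pts), Ld)])
    verts.append(outlet_v)
    tris.append(offset + dk_tris)
    tags.append(np.full(len(dk_tris), PATCH_OUTLET))
    offset += len(outlet_v)
    cap_v = np.column_stack([dk_pts, np.full(len(dk_pts), -Lp)])
    verts.append(cap_v)
    tris.append(offset + dk_tris[:, [0, 2, 1]])  # outward normal -z
    tags.append(np.full(len(dk_tris), PATCH_CAP))

    verts = np.concatenate(verts)
    tris = np.concatenate(tris)
    tags = np.concatenate(tags)
    verts, tris, ok = _weld(verts, tris)
    tris, tags = tris[ok], tags[ok]

    toe = curve[np.argmax(curve[:, 2])]
    heel = curve[np.argmin(curve[:, 2])]
    orifice_centroid = curve.mean(axis=0)
    floor_z = float(orifice_centroid[2])
    surf = SurfaceGeometry(verts, tris, tags, metadata={
        "kind": "anastomosis",
        "spec": spec,
        "host_radius": ra,
        "graft_radius": rg,
        "resolution": resolution,
        "z_range": (-Lp, Ld),
        "orifice_curve": curve,
        "landmarks": {
            "toe_artery": toe.tolist(),
            "toe_graft": toe.tolist(),
            "heel": heel.tolist(),
            "floor_center": [-ra, 0.0, floor_z],
            "junction_center": [0.0, 0.0, 0.0],
        },
        "inlet_plane": {"point": (Lg * a_g).tolist(),
                        "normal": a_g.tolist()},
        "outlet_plane": {"point": [0.0, 0.0, Ld], "normal": [0.0, 0.0, 1.0]},
        "cap_plane": {"point": [0.0, 0.0, -Lp], "normal": [0.0, 0.0, -1.0]},
    })
    return surf


# ---------------------------------------------------------------------------
# Stenosis
# ---------------------------------------------------------------------------

def stenosis_warp(points: np.ndarray, host_radius: float,
                  spec_s: StenosisSpec) -> np.ndarray:
    """Radial warp implementing a cosine-tapered focal area stenosis.

    Within the axial band, radii scale by sqrt(1 - (pct/100) w(z)) with
    w(z) = (1 + cos(pi (z - z0)/E)) / 2, so a plain-tube cross-section loses
    exactly pct percent of its area at the throat.  The displacement fades
    linearly to zero between one and two host radii from the host axis so the
    graft conduit away from the junction is untouched.
    """
    p = np.array(points, dtype=float, copy=True)
    frac = spec_s.area_stenosis_pct / 100.0
    if frac == 0.0:
        return p
    z0, E = spec_s.axial_center, spec_s.axial_extent
    dz = p[:, 2] - z0
    in_band = np.abs(dz) < E
    if not np.any(in_band):
        return p
    w = 0.5 * (1.0 + np.cos(np.pi * dz[in_band] / E))
    f = np.sqrt(1.0 - frac * w)
    rho = np.hypot(p[in_band, 0], p[in_band, 1])
    # smooth (cosine) radial fade between one and two host radii
    t = np.clip(rho / host_radius - 1.0, 0.0, 1.0)
    lam = 0.5 * (1.0 + np.cos(np.pi * t))
    lam[rho <= host_radius] = 1.0
    scale = 1.0 - lam * (1.0 - f)
    p[in_band, 0] *= scale
    p[in_band, 1] *= scale
    return p


def stenosis_unwarp(points: np.ndarray, host_radius: float,
                    spec_s: StenosisSpec, n_iter: int = 60) -> np.ndarray:
    """Inverse of :func:`stenosis_warp` by bisection on the (strictly
    monotone) radial map."""
    p = np.array(points, dtype=float, copy=True)
    frac = spec_s.area_stenosis_pct / 100.0
    if frac == 0.0:
        return p
    z0, E = spec_s.axial_center, spec_s.axial_extent
    dz = p[:, 2] - z0
    in_band = np.abs(dz) < E
    if not np.any(in_band):
        return p
    w = 0.5 * (1.0 + np.cos(np.pi * dz[in_band] / E))
    f = np.sqrt(1.0 - frac * w)
    rho = np.hypot(p[in_band, 0], p[in_band, 1])

    def fwd(rho0):
        t = np.clip(rho0 / host_radius - 1.0, 0.0, 1.0)
        lam = 0.5 * (1.0 + np.cos(np.pi * t))
        lam[rho0 <= host_radius] = 1.0
        return rho0 * (1.0 - lam * (1.0 - f))

    lo = rho.copy()
    hi = rho / f   # radii shrink by at most the throat factor
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        too_small = fwd(mid) < rho
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
    rho0 = 0.5 * (lo + hi)
    ratio = np.divide(rho0, rho, out=np.ones_like(rho), where=rho > 0)
    p[in_band, 0] *= ratio
    p[in_band, 1] *= ratio
    return p


def apply_stenosis(surface: SurfaceGeometry, spec_a: AnastomosisSpec | None,
                   spec_s: StenosisSpec) -> SurfaceGeometry:
    """Narrow the host conduit by the cosine warp; patches stay untouched."""
    out = surface.copy()
    if spec_s.area_stenosis_pct == 0.0:
        return out
    ra = (spec_a.host_radius if spec_a is not None
          else surface.metadata["host_radius"])
    z_lo, z_hi = surface.metadata["z_range"]
    lo = spec_s.axial_center - spec_s.axial_extent
    hi = spec_s.axial_center + spec_s.axial_extent
    if lo <= z_lo or hi >= z_hi:
        raise ValueError(
            f"stenosis band [{lo:.3g}, {hi:.3g}] overlaps an end plane of "
            f"the host segment [{z_lo:.3g}, {z_hi:.3g}]")
    out.vertices = stenosis_warp(surface.vertices, ra, spec_s)
    out.metadata["stenosis"] = spec_s
    return out


def _slice_wall_loop(surface: SurfaceGeometry, z: float):
    """Intersect wall triangles with the plane z=const.

    Returns the ordered polygon (n, 2) if the section is a single closed
    loop, or None if the section is open (slice through the orifice).
    """
    v = surface.vertices
    wall = surface.triangles[surface.patch_tags == PATCH_WALL]
    dz = v[:, 2] - z
    side = dz[wall]
    crossing = ~((side > 0).all(axis=1) | (side < 0).all(axis=1))
    pts = []
    edge_count: dict = {}
    for tri in wall[crossing]:
        cut = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            da, db = dz[a], dz[b]
            if (da > 0) != (db > 0):
                t = da / (da - db)
                q = v[a] + t * (v[b] - v[a])
                key = (min(a, b), max(a, b))
                edge_count[key] = edge_count.get(key, 0) + 1
                cut.append(q[:2])
        if len(cut) == 2:
            pts.append(cut)
    if not pts:
        return None
    if any(c != 2 for c in edge_count.values()):
        return None  # open section: the cut reaches a free rim (orifice)
    seg = np.asarray(pts).reshape(-1, 2)
    center = seg.mean(axis=0)
    ang = np.arctan2(seg[:, 1] - center[1], seg[:, 0] - center[0])
    order = np.argsort(ang)
    poly = seg[order]
    return poly[::2]  # each cut point appears twice (shared edges)


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def measure_area_stenosis(surface: SurfaceGeometry,
                          spec_a: AnastomosisSpec | None = None,
                          n_slices: int = 80) -> float:
    """Percent area reduction at the tightest host cross-section.

    Slices the wall perpendicular to the host axis; open sections (through
    the junction orifice) are skipped.  The reference area is the slice
    closest to the outlet, so surface faceting cancels in the ratio.
    """
    z_lo, z_hi = surface.metadata["z_range"]
    margin = 2.5 * surface.metadata.get("resolution", (z_hi - z_lo) / 40)
    stations = np.linspace(z_lo + margin, z_hi - margin, n_slices)
    areas = {}
    for z in stations:
        poly = _slice_wall_loop(surface, z)
        if poly is not None and len(poly) >= 3:
            areas[z] = _polygon_area(poly)
    if not areas:
        raise ValueError("no closed host cross-section found while slicing")
    ref = areas[max(areas)]  # most distal closed slice
    z_min = min(areas, key=areas.get)
    # refine around the coarse minimum to land on the throat
    dz = stations[1] - stations[0]
    for z in np.linspace(z_min - dz, z_min + dz, 41):
        poly = _slice_wall_loop(surface, z)
        if poly is not None and len(poly) >= 3:
            areas[z] = _polygon_area(poly)
    a_min = min(areas.values())
    return float(100.0 * (1.0 - a_min / ref))


def classify_stenosis(pct: float) -> str:
    """Severity classes: <20 small, 20-40 moderate_gap, 40-60 mild, >60
    severe (boundaries closed on the left)."""
    if not 0.0 <= pct < 100.0:
        raise ValueError("percent stenosis must lie in [0, 100)")
    if pct < 20.0:
        return "small"
    if pct < 40.0:
        return "moderate_gap"
    if pct <= 60.0:
        return "mild"
    return "severe"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stl(surface: SurfaceGeometry, path: str | Path) -> None:
    """Binary STL (normals recomputed; patch tags are not representable)."""
    path = Path(path)
    v = surface.vertices
    t = surface.triangles
    n = surface.triangle_normals()
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    with open(path, "wb") as fh:
        fh.write(b"graftflow surface".ljust(80, b"\0"))
        fh.write(struct.pack("<I", len(t)))
        rec = np.zeros((len(t), 12), dtype="<f4")
        rec[:, 0:3] = n
        rec[:, 3:6] = v[t[:, 0]]
        rec[:, 6:9] = v[t[:, 1]]
        rec[:, 9:12] = v[t[:, 2]]
        raw = np.zeros((len(t), 50), dtype=np.uint8)
        raw[:, :48] = rec.view(np.uint8).reshape(len(t), 48)
        fh.write(raw.tobytes())


def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    """Two-column CSV (t_seconds, velocity_cm_per_s) + JSON sidecar."""
    path = Path(path)
    arr = np.column_stack([w.sample_times, w.sample_velocities])
    header = "t_seconds,velocity_cm_per_s"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
    sidecar = {"period_s": w.period, "mean_velocity_cm_s": w.mean_velocity,
               "n_samples": int(len(w.sample_times)), "fourier": w.fourier}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))
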