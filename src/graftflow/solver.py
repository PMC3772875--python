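"""Stabilized finite-element solver for incompressible Newtonian flow.

Discretization: equal-order linear (P1-P1) velocity/pressure on tetrahedra
with SUPG/PSPG stabilization (element tau from size, local velocity and time
step), backward-Euler time integration, and Picard (lagged-convection)
linearization.  Boundary conditions follow the bypass-graft setting: a blunt
(plug) velocity profile on the inlet plane with the no-slip rim prevailing,
no-slip on wall and occluded cap, and a homogeneous natural (zero
pseudo-traction) condition on the outlet.

The momentum equation is assembled in the Laplacian (pseudo-traction) form

    rho du/dt + rho (u.grad)u = -grad p + mu lap u,

continuity  div u = 0, all in CGS units (cm, s, g, dyne).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from graftflow.geometry import (
    PATCH_CAP,
    PATCH_INLET,
    PATCH_OUTLET,
    PATCH_WALL,
    FluidProperties,
    Waveform,
)
from graftflow.meshing import VolumeMesh

__all__ = [
    "SolverSettings",
    "FlowField",
    "FlowSeries",
    "SolverError",
    "solve_steady",
    "solve_transient",
    "flux_balance",
    "check_cycle_periodicity",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    """Time-stepping and nonlinear-iteration controls.

    The reference temporal resolution is dt = 0.00695 s with 121 steps per
    cardiac cycle and three cycles; the desk tier runs two cycles with the
    periodicity check as a guard.
    """

    dt: float = 0.00695
    steps_per_cycle: int = 121
    n_cycles: int = 3
    picard_tol: float = 1e-4
    picard_max_iter: int = 20
    linear_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        if self.dt <= 0 or self.steps_per_cycle < 2:
            raise ValueError("invalid time discretization")

    @property
    def period(self) -> float:
        return self.dt * self.steps_per_cycle

    def check_waveform(self, waveform: Waveform) -> None:
        if abs(self.period - waveform.period) > 1e-9 * waveform.period:
            raise ValueError(
                f"dt * steps_per_cycle = {self.period} does not match the "
                f"waveform period {waveform.period}")

    @classmethod
    def for_waveform(cls, waveform: Waveform, steps_per_cycle: int = 121,
                     n_cycles: int = 3, **kw) -> "SolverSettings":
        return cls(dt=waveform.period / steps_per_cycle,
                   steps_per_cycle=steps_per_cycle, n_cycles=n_cycles, **kw)


@dataclass
class FlowField:
    """Nodal velocity (cm/s) and pressure (dyne/cm^2) at one instant."""

    velocity: np.ndarray   # (N, 3)
    pressure: np.ndarray   # (N,)
    time: float = 0.0


@dataclass
class FlowSeries:
    """Velocity/pressure snapshots covering exactly the final cycle
    (steps_per_cycle + 1 entries, closed cycle)."""

    times: np.ndarray         # (S,)
    velocity: np.ndarray      # (S, N, 3)
    pressure: np.ndarray      # (S, N)
    settings: SolverSettings
    mesh: VolumeMesh
    previous_cycle: "FlowSeries | None" = None

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def field(self, s: int) -> FlowField:
        return FlowField(self.velocity[s], self.pressure[s],
                         float(self.times[s]))


# ---------------------------------------------------------------------------
# assembly machinery
# ---------------------------------------------------------------------------

class _Discretization:
    """Precomputed element data and Dirichlet sets for one mesh."""

    def __init__(self, mesh: VolumeMesh, props: FluidProperties):
        self.mesh = mesh
        self.props = props
        nodes, tets = mesh.nodes, mesh.tets
        x = nodes[tets]                      # (E, 4, 3)
        e10 = x[:, 1] - x[:, 0]
        e20 = x[:, 2] - x[:, 0]
        e30 = x[:, 3] - x[:, 0]
        vol = np.einsum("ij,ij->i", e10, np.cross(e20, e30)) / 6.0
        if np.any(vol <= 0):
            raise SolverError("mesh contains non-positive tet volumes")
        self.vol = vol
        # P1 basis gradients: rows of the inverse Jacobian
        J = np.stack([e10, e20, e30], axis=1)        # (E, 3, 3)
        Jinv = np.linalg.inv(J)                      # (E, 3, 3)
        g = np.empty((len(tets), 4, 3))
        g[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
        g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
        self.grad = g
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        el = np.stack([np.linalg.norm(x[:, a] - x[:, b], axis=1)
                       for a, b in edges], axis=1)
        self.h = np.sqrt((el ** 2).mean(axis=1))     # rms edge length
        self.tets = tets
        self.n = len(nodes)

        # COO scatter indices for (4, 4) element blocks
        self.rows = np.repeat(tets, 4, axis=1).reshape(-1)     # k index
        self.cols = np.tile(tets, (1, 4)).reshape(-1)          # j index

        # Dirichlet sets: wall + cap no-slip; inlet plug (rim stays no-slip)
        wall = set(mesh.boundary_nodes(PATCH_WALL))
        wall |= set(mesh.boundary_nodes(PATCH_CAP))
        inlet = [v for v in mesh.boundary_nodes(PATCH_INLET) if v not in wall]
        self.noslip = np.array(sorted(wall), dtype=int)
        self.inlet = np.array(inlet, dtype=int)
        n_out = np.asarray(mesh.metadata.get(
            "inlet_plane", {}).get("normal", [0.0, 0.0, -1.0]), dtype=float)
        self.inflow_dir = -n_out / np.linalg.norm(n_out)

        # flux-preserving plug: the no-slip rim removes part of the discrete
        # inflow integral, so the interior plug value is scaled to make the
        # delivered flux equal (mean velocity) x (inlet area) exactly
        inlet_faces = mesh.boundary_faces[mesh.boundary_tags == PATCH_INLET]
        _, areas = mesh.face_normals_areas()
        a_in = areas[mesh.boundary_tags == PATCH_INLET]
        interior = np.zeros(self.n)
        interior[self.inlet] = 1.0
        q_unit = float((a_in * interior[inlet_faces].mean(axis=1)).sum())
        self.inlet_scale = float(a_in.sum() / q_unit) if q_unit > 0 else 1.0

        # static element matrices
        V = vol[:, None, None]
        self.K = (props.mu * V) * np.einsum("eki,eji->ekj", g, g)
        M = np.full((4, 4), 1.0 / 20.0)
        np.fill_diagonal(M, 1.0 / 10.0)
        self.M = V * M[None, :, :]                   # consistent mass
        self.int_phi = vol[:, None] / 4.0            # (E, 4)

    def element_convection(self, u: np.ndarray):
        """Element-mean advection velocity from nodal field u."""
        return u[self.tets].mean(axis=1)             # (E, 3)

    def tau_bar(self, a_e: np.ndarray, dt: float | None):
        """Stabilization parameter tau/rho (s cm^3/g); finite for rho=0.

        The time-step term is deliberately excluded so the transient
        operator reduces exactly to the steady one in the steady limit
        (the classic small-time-step PSPG inconsistency)."""
        mu, rho = self.props.mu, self.props.rho
        h = self.h
        term_v = (12.0 * mu / h ** 2) ** 2
        term_a = (2.0 * rho * np.linalg.norm(a_e, axis=1) / h) ** 2
        return 1.0 / np.sqrt(term_a + term_v)

    def assemble(self, a: np.ndarray, dt: float | None,
                 u_old: np.ndarray | None):
        """System matrix (4N x 4N) and rhs for one Picard iteration.

        a : (N, 3) lagged advection field; dt None for steady;
        u_old : previous time-step velocity (transient rhs).
        """
        n = self.n
        mu, rho = self.props.mu, self.props.rho
        g, V, tets = self.grad, self.vol, self.tets
        a_e = self.element_convection(a)
        tb = self.tau_bar(a_e, dt)
        ag = np.einsum("ei,eki->ek", a_e, g)          # (E, 4): a . grad phi_k
        Vc = V[:, None, None]

        blocks_r, blocks_c, blocks_d = [], [], []

        def add(row_off, col_off, data):
            blocks_r.append(self.rows + row_off * n)
            blocks_c.append(self.cols + col_off * n)
            blocks_d.append(data.reshape(-1))

        # momentum diagonal blocks (identical for the three components)
        A = self.K.copy()
        if rho > 0:
            A += (rho * Vc / 4.0) * ag[:, None, :]                   # Galerkin
            A += (tb * rho ** 2 * V)[:, None, None] * \
                np.einsum("ek,ej->ekj", ag, ag)                      # SUPG conv
        if dt is not None:
            A += (rho / dt) * self.M
            if rho > 0:
                A += ((tb * rho ** 2 / dt * V / 4.0)[:, None]
                      * ag)[:, :, None] * np.ones((1, 1, 4))         # SUPG mass
        for i in range(3):
            add(i, i, A)

        rhs = np.zeros(4 * n)
        if dt is not None and u_old is not None:
            ue = u_old[tets]                                          # (E,4,3)
            for i in range(3):
                # Galerkin mass rhs
                Fi = (rho / dt) * np.einsum("ekj,ej->ek", self.M, ue[:, :, i])
                if rho > 0:
                    Fi += (tb * rho ** 2 / dt)[:, None] * ag * \
                        (self.int_phi * ue[:, :, i]).sum(axis=1)[:, None]
                np.add.at(rhs, tets.reshape(-1) + i * n, Fi.reshape(-1))

        for i in range(3):
            # pressure gradient in momentum: -(p, d v_i/dx_i)
            Gp = -(Vc[:, :, 0] / 4.0 * g[:, :, i])[:, :, None] * \
                np.ones((1, 1, 4))
            if rho > 0:
                Gp += (tb * rho * V)[:, None, None] * \
                    np.einsum("ek,ej->ekj", ag, g[:, :, i])          # SUPG p
            add(i, 3, Gp)

            # continuity: (div u, q) + PSPG momentum residual
            Dl = (Vc[:, 0, :] / 4.0 * g[:, :, i])[:, None, :] * \
                np.ones((1, 4, 1))
            if rho > 0:
                Dl += (tb * rho * V)[:, None, None] * \
                    np.einsum("ek,ej->ekj", g[:, :, i], ag)          # PSPG conv
            if dt is not None and rho > 0:
                Dl += ((tb * rho / dt * V / 4.0)[:, None]
                       * g[:, :, i])[:, :, None] * np.ones((1, 1, 4))
            add(3, i, Dl)

        # PSPG pressure Laplacian
        Ppp = (tb * V)[:, None, None] * np.einsum("eki,eji->ekj", g, g)
        add(3, 3, Ppp)

        if dt is not None and u_old is not None and rho > 0:
            ue = u_old[tets]
            Fq = (tb * rho / dt)[:, None, None] * g * \
                (self.int_phi[:, :, None] * ue).sum(axis=1)[:, None, :]
            np.add.at(rhs, tets.reshape(-1) + 3 * n,
                      Fq.sum(axis=2).reshape(-1))

        mat = sp.coo_matrix(
            (np.concatenate(blocks_d),
             (np.concatenate(blocks_r), np.concatenate(blocks_c))),
            shape=(4 * n, 4 * n)).tocsr()
        return mat, rhs

    def apply_dirichlet(self, mat: sp.csr_matrix, rhs: np.ndarray,
                        inlet_speed: float):
        n = self.n
        fixed = []
        vals = []
        for i in range(3):
            fixed.append(self.noslip + i * n)
            vals.append(np.zeros(len(self.noslip)))
            fixed.append(self.inlet + i * n)
            vals.append(np.full(len(self.inlet),
                                inlet_speed * self.inlet_scale
                                * self.inflow_dir[i]))
        fixed = np.concatenate(fixed)
        vals = np.concatenate(vals)
        # zero the constrained rows, set unit diagonal
        d = np.ones(4 * n)
        d[fixed] = 0.0
        mat = sp.diags(d) @ mat + sp.diags(
            np.where(d == 0.0, 1.0, 0.0))
        rhs = rhs.copy()
        rhs[fixed] = vals
        return mat.tocsc(), rhs


def _factorize(mat):
    try:
        return splu(mat)
    except RuntimeError as exc:  # pragma: no cover - singular matrix
        raise SolverError(f"sparse factorization failed: {exc}") from exc


def _picard_step(disc, x0, v_in, dt, u_old, tol, max_iter, lu_box):
    """Drive one (pseudo-)time level to its Picard fixed point.

    Uses LU-preconditioned defect correction so a factorization from an
    earlier step can be reused: each iteration assembles the current Picard
    matrix, applies one correction x += LU^-1 (b - A x), and refactorizes
    only when the contraction stalls.  lu_box is a 1-element list holding
    the reusable factorization.
    """
    n = disc.n
    x = x0.copy()
    a = x[:3 * n].reshape(3, n).T
    deltas = []
    for it in range(max_iter):
        mat, rhs = disc.assemble(a, dt=dt, u_old=u_old)
        mat, rhs = disc.apply_dirichlet(mat, rhs, v_in)
        if lu_box[0] is None:
            lu_box[0] = _factorize(mat)
            fresh = True
        else:
            fresh = False
        x_new = x + lu_box[0].solve(rhs - mat @ x)
        u_new = x_new[:3 * n].reshape(3, n).T
        delta = (np.linalg.norm(u_new - a)
                 / max(np.linalg.norm(u_new), 1e-30))
        deltas.append(delta)
        if delta < tol:
            return x_new, deltas
        stalled = (len(deltas) >= 2 and delta > 0.5 * deltas[-2])
        if stalled and not fresh:
            lu_box[0] = _factorize(mat)
            x_new = x + lu_box[0].solve(rhs - mat @ x)
            u_new = x_new[:3 * n].reshape(3, n).T
            delta = (np.linalg.norm(u_new - a)
                     / max(np.linalg.norm(u_new), 1e-30))
            deltas[-1] = delta
            if delta < tol:
                return x_new, deltas
        x = x_new
        a = u_new
    raise SolverError(
        f"Picard iteration stalled; relative-change history: "
        f"{[f'{d:.2e}' for d in deltas]}")


# ---------------------------------------------------------------------------
# public solvers
# ---------------------------------------------------------------------------

def solve_steady(mesh: VolumeMesh, props: FluidProperties,
                 inlet_speed: float,
                 picard_tol: float = 1e-4,
                 picard_max_iter: int = 30) -> FlowField:
    """Steady flow with a plug inlet at ``inlet_speed`` (cm/s)."""
    if inlet_speed < 0:
        raise ValueError("inlet_speed must be non-negative")
    n = mesh.n_nodes
    if inlet_speed == 0.0:
        return FlowField(np.zeros((n, 3)), np.zeros(n))
    disc = _Discretization(mesh, props)
    lu_box = [None]
    x, _ = _picard_step(disc, np.zeros(4 * n), inlet_speed, None, None,
                        picard_tol, picard_max_iter, lu_box)
    return FlowField(x[:3 * n].reshape(3, n).T, x[3 * n:])


def solve_transient(mesh: VolumeMesh, props: FluidProperties,
                    waveform: Waveform, settings: SolverSettings,
                    keep_previous_cycle: bool = False,
                    verbose: bool = False) -> FlowSeries:
    """Backward-Euler stepping from rest through ``settings.n_cycles``
    cycles; returns the final cycle (and optionally the one before)."""
    settings.check_waveform(waveform)
    disc = _Discretization(mesh, props)
    n = mesh.n_nodes
    spc = settings.steps_per_cycle
    dt = settings.dt
    total = spc * settings.n_cycles

    u = np.zeros((n, 3))
    p = np.zeros(n)
    kept: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    first_kept = (settings.n_cycles - (2 if keep_previous_cycle else 1)) * spc
    if first_kept == 0:
        kept[0] = (u.copy(), p.copy())  # from-rest initial state

    lu_box = [None]
    x = np.zeros(4 * n)
    for step in range(1, total + 1):
        t = step * dt
        v_in = float(waveform.velocity_at(t))
        try:
            x, _ = _picard_step(disc, x, v_in, dt, u, settings.picard_tol,
                                settings.picard_max_iter, lu_box)
        except SolverError as exc:
            raise SolverError(f"step {step} (t={t:.4f} s): {exc}") from exc
        u, p = x[:3 * n].reshape(3, n).T, x[3 * n:]
        if step >= first_kept:
            kept[step] = (u.copy(), p.copy())
        if verbose and step % spc == 0:
            print(f"  cycle {step // spc}/{settings.n_cycles} done")

    def make_series(c0: int, prev=None) -> FlowSeries:
        steps = range(c0, c0 + spc + 1)
        times = np.array([s * dt for s in steps])
        vel = np.stack([kept[s][0] for s in steps])
        pre = np.stack([kept[s][1] for s in steps])
        return FlowSeries(times, vel, pre, settings, mesh,
                          previous_cycle=prev)

    prev = None
    if keep_previous_cycle:
        prev = make_series((settings.n_cycles - 2) * spc)
    return make_series((settings.n_cycles - 1) * spc, prev)


def flux_balance(fld: FlowField, mesh: VolumeMesh) -> dict:
    """Surface-integrated normal velocity per patch (cm^3/s), signed by the
    outward normal, and the continuity imbalance fraction."""
    normals, _ = mesh.face_normals_areas()
    u_face = fld.velocity[mesh.boundary_faces].mean(axis=1)
    q = np.einsum("ij,ij->i", u_face, normals)
    out = {}
    for tag, name in ((PATCH_INLET, "inlet_flux"),
                      (PATCH_OUTLET, "outlet_flux")):
        out[name] = float(q[mesh.boundary_tags == tag].sum())
    denom = abs(out["inlet_flux"])
    imbalance = (abs(out["inlet_flux"] + out["outlet_flux"]) / denom
                 if denom > 0 else 0.0)
    out["imbalance_fraction"] = float(imbalance)
    return out


def check_cycle_periodicity(series_prev: FlowSeries,
                            series_last: FlowSeries) -> float:
    """Relative L2 difference between two consecutive cycles' velocity
    snapshots (matching phase grids)."""
    if series_prev.velocity.shape != series_last.velocity.shape:
        raise ValueError("cycle snapshot grids do not match")
    num = np.linalg.norm(series_last.velocity - series_prev.velocity)
    den = np.linalg.norm(series_last.velocity)
    return float(num / max(den, 1e-30))
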