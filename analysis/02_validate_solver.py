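#!/usr/bin/env python
"""Validate the flow solver against analytic pipe-flow oracles.

Steady: plug-inlet tube at Re ~ 95 versus Poiseuille (centerline 2V, wall
shear 4 mu V / r).  Pulsatile: single-harmonic tube at Womersley number 2.8
versus the analytic Womersley series (flux-driven form).  Writes
results/validation.csv.
"""

import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from graftflow import analytic
from graftflow import geometry as geo
from graftflow import meshing, solver, wallshear

OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fluid = geo.default_fluid()
    rows = []

    # -- steady Poiseuille ------------------------------------------------
    t0 = time.time()
    mesh = meshing.tube_volume_mesh(0.15, 3.0, 0.04)
    fld = solver.solve_steady(mesh, fluid, 12.0)
    rho = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
    sel = (rho < 0.02) & (mesh.nodes[:, 2] > 2.2)
    vmax = float(np.linalg.norm(fld.velocity[sel], axis=1).max())
    ids, tau, _, interior = wallshear.wall_shear_field(fld, mesh, fluid)
    z = mesh.nodes[ids, 2]
    rw = np.hypot(mesh.nodes[ids, 0], mesh.nodes[ids, 1])
    dev = interior & (z > 2.0) & (z < 2.8) & (rw > 0.14)
    wss = float(np.linalg.norm(tau[dev], axis=1).mean())
    fb = solver.flux_balance(fld, mesh)
    rows += [
        dict(check="poiseuille_centerline", value=vmax,
             reference=analytic.poiseuille_centerline(12.0),
             rel_error=abs(vmax - 24.0) / 24.0,
             runtime_s=time.time() - t0),
        dict(check="poiseuille_wall_shear", value=wss,
             reference=analytic.poiseuille_wall_shear(fluid.mu, 12.0, 0.15),
             rel_error=abs(wss - 12.8) / 12.8, runtime_s=time.time() - t0),
        dict(check="steady_flux_imbalance",
             value=fb["imbalance_fraction"], reference=0.0,
             rel_error=fb["imbalance_fraction"],
             runtime_s=time.time() - t0),
    ]

    # -- pulsatile Womersley ----------------------------------------------
    t0 = time.time()
    r, L = 0.15, 1.2
    T = 2 * math.pi * fluid.rho * r * r / (fluid.mu * 2.8 ** 2)
    amps, phases = (0.5,), (0.0,)
    wf = geo.synthesize_inlet_waveform(4.0, T, amps, phases, n_samples=100)
    mesh = meshing.tube_volume_mesh(r, L, 0.04)
    settings = solver.SolverSettings.for_waveform(wf, steps_per_cycle=100,
                                                  n_cycles=3)
    series = solver.solve_transient(mesh, fluid, wf, settings)
    sel = np.abs(mesh.nodes[:, 2] - 0.88) < 1e-9
    rr = np.hypot(mesh.nodes[sel, 0], mesh.nodes[sel, 1])
    err = den = 0.0
    for s, t in enumerate(series.times):
        ua = analytic.womersley_profile(rr, t, r, T, 4.0, amps, phases,
                                        fluid.nu)
        err += ((series.velocity[s, sel, 2] - ua) ** 2).sum()
        den += (ua ** 2).sum()
    l2 = math.sqrt(err / den)
    imb = max(solver.flux_balance(series.field(s), mesh)
              ["imbalance_fraction"] for s in range(series.n_snapshots))
    rows += [
        dict(check="womersley_profile_l2", value=l2, reference=0.0,
             rel_error=l2, runtime_s=time.time() - t0),
        dict(check="pulsatile_flux_imbalance", value=imb, reference=0.0,
             rel_error=imb, runtime_s=time.time() - t0),
    ]

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "validation.csv", index=False, float_format="%.6g")
    print(table.to_string(index=False))
    print("\nall relative errors:",
          ", ".join(f"{r['check']}={r['rel_error']:.2%}" for r in rows))


if __name__ == "__main__":
    main()
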