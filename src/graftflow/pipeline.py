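"""Case orchestration: geometry -> stenosis -> mesh -> transient solve ->
wall indices -> regions -> report, plus the two comparison experiments
(stenosis-severity sweep and the 2 x 2 idealized geometry sweep).

Every run is deterministic given its configuration (the only randomness is
the mesher's lattice jitter, seeded from the config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from graftflow import geometry as geo
from graftflow import meshing, regions, solver, wallshear
from graftflow.config import CaseConfig

__all__ = ["CaseResult", "run_case", "run_severity_experiment",
           "run_idealized_sweep", "region_values"]

BAND_LABELS = ("stenotic_band", "proximal_band", "distal_band")
REGION_LABELS = ("A", "B", "C", "D")
INDICES = ("TAWSS", "OSI", "WSSG")
UNITS = {"TAWSS": "dyne/cm^2", "OSI": "-", "WSSG": "dyne/cm^3"}


@dataclass
class CaseResult:
    """In-memory results of one case run (the CaseReport payload)."""

    config: CaseConfig
    mesh: meshing.VolumeMesh
    series: solver.FlowSeries
    maps: wallshear.WallMaps
    masks: dict | None
    stats: pd.DataFrame | None
    dimensionless: wallshear.DimensionlessSummary
    periodicity: float
    max_flux_imbalance: float
    mesh_quality: dict
    stenosis_class: str

    def report_dict(self) -> dict:
        d = {
            "config": self.config.to_dict(),
            "units": {"length": "cm", "time": "s", "velocity": "cm/s",
                      "pressure": "dyne/cm^2", "wss": "dyne/cm^2",
                      "wssg": "dyne/cm^3", "area": "mm^2"},
            "dimensionless": {
                "re_mean": self.dimensionless.re_mean,
                "re_peak": self.dimensionless.re_peak,
                "womersley": self.dimensionless.womersley,
            },
            "mesh": {k: self.mesh_quality[k] for k in
                     ("n_nodes", "n_tets", "min_radius_ratio",
                      "median_radius_ratio", "total_volume")},
            "periodicity_metric": self.periodicity,
            "max_flux_imbalance": self.max_flux_imbalance,
            "stenosis_class": self.stenosis_class,
        }
        if self.stats is not None:
            d["region_stats"] = self.stats.to_dict(orient="records")
        return d


def _build_mesh(cfg: CaseConfig) -> meshing.VolumeMesh:
    if cfg.kind == "tube":
        return meshing.tube_volume_mesh(
            cfg.host_diameter_cm / 2.0, cfg.tube_length_cm, cfg.edge,
            stenosis=cfg.stenosis_spec())
    return meshing.anastomosis_volume_mesh(
        cfg.anastomosis_spec(), cfg.stenosis_spec(), cfg.edge, seed=cfg.seed)


def region_values(maps: wallshear.WallMaps, mask: regions.RegionMask,
                  index: str) -> np.ndarray:
    """Raw per-node values of an index over a region mask."""
    lookup = -np.ones(int(maps.wall_node_ids.max()) + 1, dtype=int)
    lookup[maps.wall_node_ids] = np.arange(len(maps.wall_node_ids))
    idx = lookup[mask.wall_node_ids]
    return getattr(maps, index.lower())[idx[idx >= 0]]


def run_case(cfg: CaseConfig, write_outputs: bool = True,
             verbose: bool = False) -> CaseResult:
    """Execute the full pipeline for one case."""
    props = cfg.fluid()
    wf = cfg.waveform()
    mesh = _build_mesh(cfg)
    quality = meshing.validate_mesh(mesh)

    settings = cfg.solver_settings()
    series = solver.solve_transient(mesh, props, wf, settings,
                                    keep_previous_cycle=True,
                                    verbose=verbose)
    periodicity = solver.check_cycle_periodicity(series.previous_cycle,
                                                 series)
    imb = max(solver.flux_balance(series.field(s), mesh)
              ["imbalance_fraction"] for s in range(series.n_snapshots))

    maps = wallshear.compute_wall_maps(series, mesh, props)
    dimless = wallshear.dimensionless_numbers(
        wf, 2.0 * cfg.anastomosis_spec().graft_radius
        if cfg.kind == "anastomosis" else cfg.host_diameter_cm, props)

    masks = None
    stats = None
    if cfg.kind == "anastomosis":
        spec = cfg.anastomosis_spec()
        lm = regions.locate_landmarks(mesh, spec)
        masks = regions.build_region_masks(
            mesh, lm, spec, radius_factor=cfg.radius_factor,
            throat_z=cfg.center_cm if cfg.area_pct > 0 else None)
        rows = []
        for label, mask in masks.items():
            for index in INDICES:
                st = regions.region_summary(maps, mask, index)
                rows.append({
                    "region": label, "index": index, "unit": UNITS[index],
                    "mean": st.mean, "sd": st.sd, "n_nodes": st.n_nodes,
                    "area_mm2": st.area_mm2,
                    "area_weighted_mean": st.area_weighted_mean,
                })
        stats = pd.DataFrame(rows)

    result = CaseResult(
        config=cfg, mesh=mesh, series=series, maps=maps, masks=masks,
        stats=stats, dimensionless=dimless, periodicity=periodicity,
        max_flux_imbalance=imb, mesh_quality=quality,
        stenosis_class=geo.classify_stenosis(cfg.area_pct),
    )
    if write_outputs:
        _write_case_outputs(result)
    return result


def _write_case_outputs(res: CaseResult) -> None:
    out = Path(res.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.config.to_yaml(out / "config.yaml")
    geo.write_waveform_csv(res.config.waveform(), out / "waveform.csv")
    Path(out / "report.json").write_text(
        json.dumps(res.report_dict(), indent=2, sort_keys=True))
    if res.stats is not None:
        res.stats.to_csv(out / "region_stats.csv", index=False,
                         float_format="%.10g")
    # wall index maps: CSV and a VTK snapshot of the final instant
    ids = res.maps.wall_node_ids
    xyz = res.mesh.nodes[ids]
    df = pd.DataFrame({
        "node_id": ids, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "tawss": res.maps.tawss, "osi": res.maps.osi, "wssg": res.maps.wssg,
    })
    df.to_csv(out / "wall_maps.csv", index=False, float_format="%.10g")
    from graftflow import mesh_io
    n = res.mesh.n_nodes
    tawss = np.zeros(n)
    osi = np.zeros(n)
    wssg = np.zeros(n)
    tawss[ids] = res.maps.tawss
    osi[ids] = res.maps.osi
    wssg[ids] = res.maps.wssg
    mesh_io.write_vtk_fields(res.mesh, out / "wall_maps.vtk", {
        "TAWSS": tawss, "OSI": osi, "WSSG": wssg,
        "velocity_final": res.series.velocity[-1],
        "pressure_final": res.series.pressure[-1],
    })


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _with(cfg: CaseConfig, **kw) -> CaseConfig:
    d = cfg.to_dict()
    d.update(kw)
    return CaseConfig.from_dict(d)


def run_severity_experiment(base: CaseConfig, severities,
                            write_outputs: bool = True,
                            verbose: bool = False):
    """Run the same anastomosis at several area-stenosis severities and
    compare band/toe/heel statistics (paired two-sample t tests)."""
    severities = list(severities)
    if len(severities) < 2:
        raise ValueError("need at least two severities")
    results = {}
    for pct in severities:
        sub = _with(base, area_pct=float(pct),
                    output_dir=str(Path(base.output_dir)
                                   / f"severity_{pct:g}"))
        results[pct] = run_case(sub, write_outputs=write_outputs,
                                verbose=verbose)

    labels = list(BAND_LABELS) + ["A", "C"]
    rows = []
    for pct, res in results.items():
        for label in labels:
            mask = res.masks[label]
            for index in INDICES:
                st = regions.region_summary(res.maps, mask, index)
                rows.append({"severity_pct": pct, "region": label,
                             "index": index, "mean": st.mean, "sd": st.sd,
                             "n_nodes": st.n_nodes,
                             "stenosis_class": res.stenosis_class})
    table = pd.DataFrame(rows)

    tests = []
    base_pct = severities[0]
    for pct in severities[1:]:
        for label in labels:
            for index in INDICES:
                va = region_values(results[base_pct].maps,
                                   results[base_pct].masks[label], index)
                vb = region_values(results[pct].maps,
                                   results[pct].masks[label], index)
                tt = regions.two_sample_t_test(va, vb)
                tests.append({
                    "pair": f"{base_pct:g}_vs_{pct:g}", "region": label,
                    "index": index, "t": tt.t_statistic,
                    "df": tt.degrees_of_freedom, "p": tt.p_value,
                    "significant": tt.significant,
                })
    tests = pd.DataFrame(tests)
    if write_outputs:
        out = Path(base.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "severity_stats.csv", index=False,
                     float_format="%.10g")
        tests.to_csv(out / "severity_ttests.csv", index=False,
                     float_format="%.10g")
    return results, table, tests


def run_idealized_sweep(base: CaseConfig, write_outputs: bool = True,
                        verbose: bool = False):
    """The 2 x 2 sweep: CSA ratio {1.0, 0.5} x graft angle {45, 85} deg,
    Regions A-D statistics and pairwise t tests against the (1.0, 45 deg)
    reference."""
    cases = [(1.0, 45.0), (0.5, 45.0), (1.0, 85.0), (0.5, 85.0)]
    results = {}
    for ratio, angle in cases:
        sub = _with(base, csa_ratio=ratio, graft_angle_deg=angle,
                    area_pct=0.0,
                    output_dir=str(Path(base.output_dir)
                                   / f"ratio{ratio:g}_angle{angle:g}"))
        results[(ratio, angle)] = run_case(sub, write_outputs=write_outputs,
                                           verbose=verbose)

    rows = []
    for (ratio, angle), res in results.items():
        for label in REGION_LABELS:
            for index in INDICES:
                st = regions.region_summary(res.maps, res.masks[label],
                                            index)
                rows.append({"csa_ratio": ratio, "graft_angle_deg": angle,
                             "region": label, "index": index,
                             "mean": st.mean, "sd": st.sd,
                             "n_nodes": st.n_nodes,
                             "area_mm2": st.area_mm2})
    table = pd.DataFrame(rows)

    ref = results[(1.0, 45.0)]
    tests = []
    for key in cases[1:]:
        res = results[key]
        for label in REGION_LABELS:
            for index in INDICES:
                va = region_values(ref.maps, ref.masks[label], index)
                vb = region_values(res.maps, res.masks[label], index)
                tt = regions.two_sample_t_test(va, vb)
                tests.append({
                    "case": f"ratio{key[0]:g}_angle{key[1]:g}",
                    "region": label, "index": index, "t": tt.t_statistic,
                    "df": tt.degrees_of_freedom, "p": tt.p_value,
                    "significant": tt.significant,
                })
    tests = pd.DataFrame(tests)
    if write_outputs:
        out = Path(base.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sweep_stats.csv", index=False,
                     float_format="%.10g")
        tests.to_csv(out / "sweep_ttests.csv", index=False,
                     float_format="%.10g")
    return results, table, tests
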