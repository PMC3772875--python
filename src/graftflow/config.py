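"""Case configuration: defaults, YAML round-trip, tier handling.

Units are CGS throughout.  The two tiers formalize the gap between the
reference resolution (0.03 cm edge, three cardiac cycles) and a desk-scale
resolution (0.06 cm edge, two cycles with the cycle-periodicity check as a
guard).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from graftflow.geometry import (
    AnastomosisSpec,
    FluidProperties,
    StenosisSpec,
    Waveform,
    synthesize_inlet_waveform,
)
from graftflow.solver import SolverSettings

__all__ = ["CaseConfig", "TIERS"]

TIERS = {
    "desk": {"edge_cm": 0.06, "n_cycles": 2},
    "production": {"edge_cm": 0.03, "n_cycles": 3},
}


@dataclass
class CaseConfig:
    """Complete description of one simulation case."""

    # geometry
    kind: str = "anastomosis"            # "anastomosis" or "tube"
    host_diameter_cm: float = 0.30
    csa_ratio: float = 1.0
    graft_angle_deg: float = 45.0
    graft_length_cm: float = 0.7
    host_distal_length_cm: float = 0.9
    host_proximal_stub_length_cm: float = 0.6
    tube_length_cm: float = 3.0          # used when kind == "tube"

    # stenosis: anastomotic, spanning the junction orifice
    area_pct: float = 0.0
    extent_diameters: float = 1.5        # band half-length in host diameters
    center_cm: float = 0.0               # along host axis from the junction

    # inflow
    mean_velocity_cm_s: float = 12.0
    period_s: float = 0.84095            # 121 x 0.00695 s
    harmonic_amplitudes: tuple = (0.8, 0.35)
    harmonic_phases: tuple = (math.pi, math.pi / 2)

    # fluid
    mu_poise: float = 0.04
    rho_g_cm3: float = 1.06

    # solver
    steps_per_cycle: int = 121
    picard_tol: float = 1e-4
    picard_max_iter: int = 20

    # regions
    radius_factor: float = 0.75

    # run control
    tier: str = "desk"
    edge_cm: float | None = None         # override the tier default
    n_cycles: int | None = None
    seed: int = 0
    output_dir: str = "results/case"

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    # -- derived objects ---------------------------------------------------
    @property
    def edge(self) -> float:
        return self.edge_cm if self.edge_cm is not None \
            else TIERS[self.tier]["edge_cm"]

    @property
    def cycles(self) -> int:
        return self.n_cycles if self.n_cycles is not None \
            else TIERS[self.tier]["n_cycles"]

    def fluid(self) -> FluidProperties:
        return FluidProperties(mu=self.mu_poise, rho=self.rho_g_cm3)

    def anastomosis_spec(self) -> AnastomosisSpec:
        return AnastomosisSpec(
            host_radius=self.host_diameter_cm / 2.0,
            csa_ratio=self.csa_ratio,
            graft_angle_deg=self.graft_angle_deg,
            graft_length=self.graft_length_cm,
            host_distal_length=self.host_distal_length_cm,
            host_proximal_stub_length=self.host_proximal_stub_length_cm)

    def stenosis_spec(self) -> StenosisSpec | None:
        if self.area_pct <= 0:
            return None
        return StenosisSpec(
            area_stenosis_pct=self.area_pct,
            axial_center=self.center_cm,
            axial_extent=self.extent_diameters * self.host_diameter_cm)

    def waveform(self) -> Waveform:
        return synthesize_inlet_waveform(
            mean_velocity=self.mean_velocity_cm_s, period=self.period_s,
            harmonic_amplitudes=self.harmonic_amplitudes,
            harmonic_phases=self.harmonic_phases,
            n_samples=max(self.steps_per_cycle, 32))

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(
            dt=self.period_s / self.steps_per_cycle,
            steps_per_cycle=self.steps_per_cycle,
            n_cycles=self.cycles,
            picard_tol=self.picard_tol,
            picard_max_iter=self.picard_max_iter)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["harmonic_amplitudes"] = list(self.harmonic_amplitudes)
        d["harmonic_phases"] = list(self.harmonic_phases)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        d = dict(d)
        for key in ("harmonic_amplitudes", "harmonic_phases"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))
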