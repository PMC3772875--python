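{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "graftflow case configuration",
  "description": "YAML case file for graftflow (CGS units: cm, s, g, dyne, Poise). All keys are optional; defaults reproduce the reference desk-tier anastomosis case.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "kind": {"enum": ["anastomosis", "tube"], "default": "anastomosis"},
    "host_diameter_cm": {"type": "number", "exclusiveMinimum": 0, "default": 0.30},
    "csa_ratio": {"type": "number", "exclusiveMinimum": 0, "default": 1.0,
                  "description": "graft-to-host cross-sectional area ratio"},
    "graft_angle_deg": {"type": "number", "exclusiveMinimum": 0, "maximum": 90, "default": 45.0},
    "graft_length_cm": {"type": "number", "exclusiveMinimum": 0, "default": 0.7},
    "host_distal_length_cm": {"type": "number", "exclusiveMinimum": 0, "default": 0.9},
    "host_proximal_stub_length_cm": {"type": "number", "exclusiveMinimum": 0, "default": 0.6},
    "tube_length_cm": {"type": "number", "exclusiveMinimum": 0, "default": 3.0},
    "area_pct": {"type": "number", "minimum": 0, "exclusiveMaximum": 100, "default": 0.0,
                 "description": "focal area stenosis severity (percent)"},
    "extent_diameters": {"type": "number", "exclusiveMinimum": 0, "default": 1.5,
                         "description": "stenosis band half-length in host diameters"},
    "center_cm": {"type": "number", "default": 0.0,
                  "description": "stenosis center along the host axis from the junction"},
    "mean_velocity_cm_s": {"type": "number", "exclusiveMinimum": 0, "default": 12.0},
    "period_s": {"type": "number", "exclusiveMinimum": 0, "default": 0.84095},
    "harmonic_amplitudes": {"type": "array", "items": {"type": "number"},
                            "default": [0.8, 0.35]},
    "harmonic_phases": {"type": "array", "items": {"type": "number"},
                        "default": [3.141592653589793, 1.5707963267948966]},
    "mu_poise": {"type": "number", "exclusiveMinimum": 0, "default": 0.04},
    "rho_g_cm3": {"type": "number", "minimum": 0, "default": 1.06},
    "steps_per_cycle": {"type": "integer", "minimum": 2, "default": 121},
    "picard_tol": {"type": "number", "exclusiveMinimum": 0, "default": 1e-4},
    "picard_max_iter": {"type": "integer", "minimum": 1, "default": 20},
    "radius_factor": {"type": "number", "exclusiveMinimum": 0, "default": 0.75,
                      "description": "region disk radius as a multiple of the host radius"},
    "tier": {"enum": ["desk", "production"], "default": "desk",
             "description": "desk: 0.06 cm edge, 2 cycles; production: 0.03 cm edge, 3 cycles"},
    "edge_cm": {"type": ["number", "null"], "default": null,
                "description": "override the tier's target edge length"},
    "n_cycles": {"type": ["integer", "null"], "default": null},
    "seed": {"type": "integer", "default": 0,
             "description": "seed for the mesher's interior lattice jitter"},
    "output_dir": {"type": "string", "default": "results/case"}
  }
}
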