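#!/usr/bin/env python
"""Build the study geometries and the inlet waveform.

Generates the four idealized end-to-side anastomosis lumens
(CSA ratio {1.0, 0.5} x graft angle {45, 85} deg), the mild- and
small-stenosis variants of the reference case, and the default pulsatile
inlet waveform.  Writes STL surfaces plus a geometry summary table to
results/geometry/.
"""

from pathlib import Path

import pandas as pd

from graftflow import geometry as geo

OUT = Path("results/geometry")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []

    for ratio, angle in [(1.0, 45.0), (0.5, 45.0), (1.0, 85.0),
                         (0.5, 85.0)]:
        spec = geo.AnastomosisSpec(csa_ratio=ratio, graft_angle_deg=angle)
        surf = geo.build_anastomosis_surface(spec, resolution=0.04)
        name = f"anastomosis_ratio{ratio:g}_angle{angle:g}"
        geo.write_stl(surf, OUT / f"{name}.stl")
        lm = surf.metadata["landmarks"]
        rows.append({
            "case": name, "csa_ratio": ratio, "graft_angle_deg": angle,
            "area_stenosis_pct": 0.0,
            "watertight": surf.is_watertight(),
            "enclosed_volume_cm3": surf.enclosed_volume(),
            "toe_z_cm": lm["toe_artery"][2], "heel_z_cm": lm["heel"][2],
        })

    spec = geo.default_anastomosis_spec()
    for pct in (10.0, 50.0):
        surf = geo.build_anastomosis_surface(spec, resolution=0.04)
        sten = geo.StenosisSpec(pct)
        surf = geo.apply_stenosis(surf, spec, sten)
        name = f"anastomosis_stenosis{pct:g}"
        geo.write_stl(surf, OUT / f"{name}.stl")
        rows.append({
            "case": name, "csa_ratio": 1.0, "graft_angle_deg": 45.0,
            "area_stenosis_pct": pct,
            "watertight": surf.is_watertight(),
            "enclosed_volume_cm3": surf.enclosed_volume(),
            "toe_z_cm": surf.metadata["landmarks"]["toe_artery"][2],
            "heel_z_cm": surf.metadata["landmarks"]["heel"][2],
        })

    wf = geo.default_waveform()
    geo.write_waveform_csv(wf, OUT / "inlet_waveform.csv")
    st = geo.waveform_stats(wf)

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "geometry_summary.csv", index=False,
                 float_format="%.6g")
    print(table.to_string(index=False))
    print(f"\ninlet waveform: mean {st['mean']:.3g} cm/s, "
          f"peak {st['peak']:.3g} cm/s (peak/mean {st['peak_to_mean']:.3g}),"
          f" period {wf.period:.5g} s")
    print(f"wrote {len(rows)} surfaces and the waveform to {OUT}/")


if __name__ == "__main__":
    main()
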