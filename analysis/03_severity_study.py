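#!/usr/bin/env python
"""Stenosis-severity experiment: small (10%) versus mild (50%) anastomotic
stenosis on the reference geometry (theta 45 deg, CSA ratio 1).

Runs the desk-tier pulsatile pipeline per severity and tabulates the
stenotic/proximal/distal band and toe/heel statistics with paired t tests.
Writes results/severity/.
"""

from graftflow.config import CaseConfig
from graftflow.pipeline import run_severity_experiment


def main() -> None:
    base = CaseConfig(seed=1, output_dir="results/severity")
    results, table, tests = run_severity_experiment(base, [10.0, 50.0],
                                                    verbose=True)
    print(table.to_string(index=False))
    print()
    print(tests.to_string(index=False))

    def band(pct, label, index):
        sub = table[(table.severity_pct == pct) & (table.region == label)
                    & (table["index"] == index)]
        return float(sub["mean"].iloc[0])

    print("\nfindings:")
    print(f"  stenotic-band TAWSS: {band(10, 'stenotic_band', 'TAWSS'):.1f}"
          f" (10%) -> {band(50, 'stenotic_band', 'TAWSS'):.1f} (50%)"
          " dyne/cm^2 — the mild stenosis elevates wall shear in the throat")
    print(f"  stenotic-band OSI:   {band(10, 'stenotic_band', 'OSI'):.4f}"
          f" (10%) -> {band(50, 'stenotic_band', 'OSI'):.4f} (50%)"
          " — flow acceleration impedes reversal inside the stenosis")
    print(f"  proximal-band TAWSS: {band(50, 'proximal_band', 'TAWSS'):.1f}"
          " dyne/cm^2 — the occluded stub stays low-shear, though the heel"
          " lip inside the band is swept by the entering jet")
    for pct in (10.0, 50.0):
        res = results[pct]
        print(f"  {pct:g}%: class={res.stenosis_class}, "
              f"periodicity={res.periodicity:.3f}, "
              f"max flux imbalance={res.max_flux_imbalance:.2e}")


if __name__ == "__main__":
    main()
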