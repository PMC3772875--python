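#!/usr/bin/env python
"""Idealized-geometry sweep: CSA ratio {1.0, 0.5} x graft angle {45, 85}.

Runs the four unstenosed anastomosis cases at desk tier, tabulates Region
A-D statistics for TAWSS/OSI/WSSG, and reports the pairwise t tests
against the (ratio 1.0, 45 deg) reference.  Writes results/sweep/.
"""

from graftflow.config import CaseConfig
from graftflow.pipeline import run_idealized_sweep


def main() -> None:
    base = CaseConfig(seed=1, output_dir="results/sweep")
    results, table, tests = run_idealized_sweep(base, verbose=True)
    pivot = table.pivot_table(index=["csa_ratio", "graft_angle_deg"],
                              columns=["region", "index"], values="mean")
    print(pivot.round(3).to_string())
    print()
    print(tests.to_string(index=False))

    def mean(key, label, index):
        res = results[key]
        st = res.stats
        return float(st[(st.region == label)
                        & (st["index"] == index)]["mean"].iloc[0])

    ref = mean((1.0, 45.0), "A", "TAWSS")
    half = mean((0.5, 45.0), "A", "TAWSS")
    print("\nfindings:")
    print(f"  Region A TAWSS {ref:.1f} -> {half:.1f} dyne/cm^2 when the "
          f"CSA ratio halves ({100 * (ref - half) / ref:.0f}% decrease; "
          "the graft delivers half the flux at the same inlet velocity)")
    print(f"  Region A OSI at 85 deg / 45 deg: "
          f"{mean((1.0, 85.0), 'A', 'OSI') / mean((1.0, 45.0), 'A', 'OSI'):.2f}x")
    print(f"  Region B WSSG combined change / reference: "
          f"{mean((0.5, 85.0), 'B', 'WSSG') / mean((1.0, 45.0), 'B', 'WSSG'):.2f}x")


if __name__ == "__main__":
    main()
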