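#!/usr/bin/env python
"""Whole-cell saturation binding across expression presets.

Simulates matched total/nonspecific binding tubes for every preset, fits the
one-site hyperbola (Kd, Bmax) and the variable-slope Hill model, converts
Bmax to fmol/mg and receptors/cell, and evaluates the occupancy-span
statistic implied by the fitted Hill slopes.

Writes results/binding_fits.csv.
"""

from pathlib import Path

import pandas as pd

from grdimer.binding import occupancy_span_ratio
from grdimer.pipeline import analyze_saturation
from grdimer.presets import PRESETS
from grdimer.synth import gen_saturation
from grdimer.units import ConversionConstants, cpm_to_fmol_per_mg, gr_per_cell, transfection_correction

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def main() -> None:
    cc = ConversionConstants()
    rows = []
    for i, name in enumerate(sorted(PRESETS)):
        fit = analyze_saturation(gen_saturation(name, seed=SEED + i))
        bulk_fmol = cpm_to_fmol_per_mg(fit["bmax_cpm_per_mg"], cc)
        corrected = transfection_correction(bulk_fmol, cc.transfection_efficiency)
        rows.append({
            "preset": name,
            "kd_nM": fit["kd_nM"],
            "hill_slope": fit["hill_slope"],
            "bmax_fmol_per_mg_bulk": bulk_fmol,
            "fmol_per_mg_transfected": corrected,
            "receptors_per_cell": gr_per_cell(corrected, cc.protein_per_cell_ng),
        })
    df = pd.DataFrame(rows)
    print(df.round(2).to_string(index=False))

    wt = df.set_index("preset")
    n_low, n_high = wt.loc["grwt_low", "hill_slope"], wt.loc["grwt_high", "hill_slope"]
    print(f"\nfitted Hill slopes: low {n_low:.2f} -> high {n_high:.2f}")
    print("10-90% occupancy span shrinks "
          f"{occupancy_span_ratio(n_low, n_high):.1f}-fold at the high level")
    print("(with a 1.0 baseline the shrinkage is "
          f"{occupancy_span_ratio(1.0, n_high):.1f}-fold)")

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "binding_fits.csv", index=False)
    print(f"\nwrote {OUT / 'binding_fits.csv'}")


if __name__ == "__main__":
    main()
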