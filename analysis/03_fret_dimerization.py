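#!/usr/bin/env python
"""FRET quantification of ligand-independent dimerization.

Simulates 50 cells per wild-type preset, runs bleed-through correction,
fold-induction normalization, sigmoid time-course fitting and the
stoichiometric inversion to pre-ligand monomer/dimer percentages.

Writes results/fret_partition.csv.
"""

from pathlib import Path

import pandas as pd

from grdimer.fret import analyze_traces
from grdimer.synth import gen_fret

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 515


def main() -> None:
    rows = []
    for i, preset in enumerate(("grwt_low", "grwt_medium", "grwt_high")):
        per_cell = analyze_traces(gen_fret(preset, n_cells=50, seed=SEED + i))
        rows.append({
            "preset": preset,
            "n_cells": len(per_cell),
            "median_fold_induction": per_cell["max_fold_induction"].median(),
            "median_pct_monomers": per_cell["pct_monomers"].median(),
            "median_pct_dimers": per_cell["pct_dimers"].median(),
        })
    df = pd.DataFrame(rows)
    print(df.round(2).to_string(index=False))
    print("\nmaximal FRET fold-induction falls as expression rises because a"
          "\nlarger share of the pool is already dimeric before ligand: the"
          "\ninversion puts ~2/3 of receptors monomeric at the low level and"
          "\n~1/3 at medium/high.")
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "fret_partition.csv", index=False)
    print(f"\nwrote {OUT / 'fret_partition.csv'}")


if __name__ == "__main__":
    main()
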