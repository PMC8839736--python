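#!/usr/bin/env python
"""Generate the synthetic measurement ensembles for every study condition.

Writes the raw curve files (TSV, one per tether) under scratch/curves/ and a
small overview table under results/.  Each preset emulates one experimental
condition: PEG (10 kDa) in water pulled at 80 nm/s or dithered at 500 Hz
while retracting at 70 nm/s, and polystyrene in water / 8M urea.  Per-curve
contour lengths are log-normal, so the ensembles require the same
contour-length normalization as the experiment.
"""

import os
import sys

import numpy as np

from oscelast.synthetic import (
    builtin_presets,
    generate_oscillatory_curve,
    generate_pulling_curve,
    write_curve,
)

SEED_OFFSET = int(sys.argv[1]) if len(sys.argv) > 1 else 0

OSCILLATORY = {"peg_water_osc", "ps_water_osc", "ps_urea_osc"}


def main() -> None:
    os.makedirs("results", exist_ok=True)
    rows = ["preset\tmodel\tn_curves\tvelocity_nm_s\tmedian_L_nm\tmean_L_drawn_nm\tkind"]
    for name, preset in builtin_presets().items():
        osc = name in OSCILLATORY
        gen = generate_oscillatory_curve if osc else generate_pulling_curve
        out_dir = os.path.join("scratch", "curves", name)
        os.makedirs(out_dir, exist_ok=True)
        Ls = []
        for i in range(preset.n_curves):
            curve = gen(preset, i, seed=preset.seed + SEED_OFFSET)
            Ls.append(curve.metadata["L_true"])
            write_curve(curve, os.path.join(out_dir, f"{name}_{i:03d}.tsv"))
        rows.append(
            f"{name}\t{preset.model}\t{preset.n_curves}\t{preset.velocity}"
            f"\t{preset.contour_median}\t{np.mean(Ls):.2f}"
            f"\t{'oscillatory' if osc else 'pulling'}"
        )
        print(f"{name}: wrote {preset.n_curves} curves, mean drawn L = {np.mean(Ls):.1f} nm")
    with open("results/ensemble_overview.tsv", "w") as fh:
        fh.write("\n".join(rows) + "\n")
    print("overview -> results/ensemble_overview.tsv")


if __name__ == "__main__":
    main()
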