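#!/usr/bin/env python
"""Donor excitation selection by spectral overlap.

Generates the excitation-dependent donor emission bands (320/340/360 nm
excitation -> 420/440/456 nm emission maxima) and the acceptor molar
absorptivity band (445 nm peak), computes the overlap integral J for each
excitation and the resulting Förster distance at the measured donor quantum
yield, and selects the excitation with maximal overlap.

Writes results/overlap_selection.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from cdfret import fret
from cdfret import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    OUT.mkdir(exist_ok=True)
    cfg = syn.get_preset("low_donor")
    acceptor = syn.make_acceptor_absorptivity(cfg)
    candidates = {ex: syn.make_donor_emission(cfg, ex)
                  for ex in sorted(cfg.donor_bands)}

    rows = []
    for ex, donor in candidates.items():
        j = fret.overlap_integral(donor, acceptor)
        rows.append({
            "excitation_nm": ex,
            "emission_peak_nm": donor.wavelengths[donor.values.argmax()],
            "J_M-1cm-1nm4": j.j_nm4,
            "R0_nm_at_phi_0.54": fret.forster_distance(j.j_cm3, phi=0.54),
        })
    table = pd.DataFrame(rows)
    best = fret.select_excitation(candidates, acceptor)
    table["selected"] = table.excitation_nm == best
    table.to_csv(OUT / "overlap_selection.csv", index=False)

    print(table.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print(f"\nSelected excitation: {best:g} nm — its emission band (456 nm "
          "peak) overlaps the 445 nm acceptor absorption most strongly, "
          "maximizing J and hence R0.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
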