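#!/usr/bin/env python
"""Recompute the cultivation arithmetic of the study from its printed
inputs: concentration conversions, volumetric productivity, the fraction
of the theoretical maximum yield reached, residual methanol, and the
byproduct suppression ratio.

Outputs: results/fermentation_numbers.csv.
"""

from pathlib import Path

import pandas as pd

from methyloflux import fermentation as ferm

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    meoh = ferm.COMPOUNDS["methanol"]
    malate = ferm.COMPOUNDS["malate"]

    rows = []

    gl = ferm.vv_percent_to_gL(0.5, meoh)
    rows.append(("initial methanol, 0.5% v/v", gl, "g/L",
                 ferm.display_round(gl)))
    gl1 = ferm.vv_percent_to_gL(1.0, meoh)
    rows.append(("daily methanol feed, 1% v/v", gl1, "g/L",
                 ferm.display_round(gl1)))

    mm = ferm.gL_to_mM(6.7, malate)
    rows.append(("supplied malate, 6.7 g/L", mm, "mM", ferm.display_round(mm)))

    rate = ferm.volumetric_productivity(13.2, 4)
    rows.append(("malate productivity, 13.2 g/L over 4 d", rate, "g/L/d",
                 ferm.display_round(rate, 1)))

    initial_mM = ferm.gL_to_mM(ferm.display_round(gl), meoh)
    pct_left = ferm.percent_remaining(91.2, initial_mM)
    rows.append(("methanol remaining, 91.2 mM residual", pct_left, "%",
                 ferm.display_round(pct_left)))

    pct_theor = ferm.percent_of_theoretical(0.099, 0.25)
    rows.append(("fraction of theoretical max, 0.099 vs 0.25", pct_theor, "%",
                 ferm.display_round(pct_theor)))

    ratio = ferm.ratio_percent(0.1, 0.5)
    rows.append(("succinate byproduct vs manual feeding, 0.1 vs 0.5 g/L",
                 ratio, "%", ferm.display_round(ratio)))

    df = pd.DataFrame(rows, columns=["quantity", "raw", "unit", "displayed"])
    df.to_csv(OUT / "fermentation_numbers.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nwrote {OUT / 'fermentation_numbers.csv'}")


if __name__ == "__main__":
    main()
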