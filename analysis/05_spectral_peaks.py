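#!/usr/bin/env python
"""Point spectroscopy at inside-border biopsy sites: PpIX peak detection.

Generates fiber-probe emission spectra (500-800 nm) at the inside-border
site of every synthetic specimen, smooths them (Savitzky-Golay) and searches
the 625-645 nm window for the PpIX emission peak. Dosed specimens should
show the peak; controls should not.

Writes results/peaks.csv.
"""

from pathlib import Path

import pandas as pd

from fluormargin.pipeline import run_study
from fluormargin.synthetic import SimulationConfig

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
N_PER_GROUP = 15


def main():
    OUT.mkdir(exist_ok=True)
    res = run_study(SimulationConfig(seed=SEED, n_specimens=N_PER_GROUP),
                    collect_spectra=True)
    df = pd.DataFrame(res.peaks)
    path = OUT / "peaks.csv"
    df.to_csv(path, index=False)
    for dose, sub in df.groupby("dose_group"):
        rate = sub["present"].mean()
        wl = sub.loc[sub["present"], "peak_nm"]
        mean_wl = f", mean peak {wl.mean():.1f} nm" if len(wl) else ""
        print(f"{dose:>7}: peak detected at {rate:.0%} of inside sites "
              f"(n={len(sub)}){mean_wl}")
    print(f"-> {path}")


if __name__ == "__main__":
    main()
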