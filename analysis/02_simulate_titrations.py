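#!/usr/bin/env python
"""Simulate the two titration regimes and track peak position and width.

The nanomolar complex (preset A) shows fast/intermediate exchange: a
single peak walks from the free to the bound shift, broadening severely
near half saturation.  The femtomolar complex (preset B) is in slow
exchange: a bound peak builds up in place, proportional to the added
peptide, saturating at 1.0 equivalents — yet its line width exceeds
R2/pi because of the bound-state isomerization.
"""

import math
from pathlib import Path

import pandas as pd

from mcshape import NoPeakError, regime_presets, measure_peak, simulate_titration

OUT = Path(__file__).resolve().parent.parent / "results"

WINDOWS = {"A": (-150.0, 450.0), "B": (180.0, 320.0)}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    presets = regime_presets()
    for key, truth in presets.items():
        series = simulate_titration(
            truth.scheme, truth.spin, truth.P0, list(truth.grid), truth.acq
        )
        rows = []
        for eq, spec in series:
            try:
                pk = measure_peak(spec, WINDOWS[key])
                rows.append(
                    {"equivalents": eq, "position_hz": pk.position,
                     "fwhm_hz": pk.fwhm, "height": pk.height}
                )
            except NoPeakError:
                rows.append(
                    {"equivalents": eq, "position_hz": float("nan"),
                     "fwhm_hz": float("nan"), "height": float("nan")}
                )
        df = pd.DataFrame(rows)
        df.to_csv(OUT / f"titration_peaks_{key}.csv", index=False)
        r2_width = truth.spin.R2 / math.pi
        print(f"--- preset {key} (Kd = {truth.kd:.3g} M) ---")
        print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        sat = df[df.equivalents >= 1.3].iloc[0]
        print(
            f"saturated peak: {sat.position_hz:.1f} Hz, FWHM {sat.fwhm_hz:.1f} Hz "
            f"(R2/pi alone would give {r2_width:.1f} Hz)\n"
        )
    print(f"wrote {OUT}/titration_peaks_A.csv and titration_peaks_B.csv")


if __name__ == "__main__":
    main()
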