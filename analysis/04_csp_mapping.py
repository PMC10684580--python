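#!/usr/bin/env python
"""Chemical-shift-perturbation mapping on a synthetic residue panel.

Generates free/bound amide shift tables with a designed distribution of
perturbation strengths, runs them through the CSP pipeline (combined
1H/15N shift change, nitrogen scaled by 1/4) and verifies the binned
classification used for structure coloring.
"""

from pathlib import Path

import pandas as pd

from mcshape import csp_table, generate_shift_tables
from mcshape.io import write_csp_records

OUT = Path(__file__).resolve().parent.parent / "results"

# emulate a binding surface: a few strongly perturbed pocket residues,
# a moderate shell, and an unperturbed remainder (caps / back side)
DESIGN = {"very strong": 2, "strong": 5, "moderate": 6, "weak": 7, "none": 12}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    free, bound, expected = generate_shift_tables(bin_design=DESIGN, seed=42)
    records = csp_table(free, bound)
    write_csp_records(records, OUT / "csp_records.csv")
    counts = pd.Series([r.bin for r in records]).value_counts()
    print("designed vs classified bin counts:")
    for label, n in DESIGN.items():
        print(f"  {label:12s} designed {n:2d}  classified {counts.get(label, 0):2d}")
    mismatches = sum(1 for r, e in zip(records, expected) if r.bin != e.bin)
    print(f"{mismatches} misclassified residues; wrote {OUT / 'csp_records.csv'}")


if __name__ == "__main__":
    main()
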