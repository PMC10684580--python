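"""Titration series simulation and chemical shift perturbation mapping.

A titration follows the experimental protocol: peptide added to 250 uM
protein in 0.1 molar-equivalents steps up to 1.5 equivalents, then 0.5
steps up to 5.5.  Chemical shift perturbations combine the amide 1H and
15N shift changes between free and bound states as

    CSP = sqrt( (dHf - dHb)^2 + ((dNf - dNb)/4)^2 )   [ppm]

and are binned for structure mapping as very strong (>= 1 ppm), strong
[0.5, 1), moderate [0.25, 0.5), weak [0.11, 0.25) and none [0, 0.11).
Residues unassigned in either state are set to zero CSP but keep their
assignment flags so "zero" and "unknown" stay distinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import ExchangeScheme, MixComposition
from .lineshape import AcquisitionSettings, SpinParameters, Spectrum1D, simulate_slice

__all__ = [
    "TitrationSeries",
    "ResidueShifts",
    "CSPRecord",
    "CSP_BINS",
    "default_equivalents_grid",
    "simulate_titration",
    "csp",
    "classify_csp",
    "csp_table",
]

#: (label, lower, upper) half-open [lower, upper) bins, ppm
CSP_BINS = (
    ("very strong", 1.0, math.inf),
    ("strong", 0.5, 1.0),
    ("moderate", 0.25, 0.5),
    ("weak", 0.11, 0.25),
    ("none", 0.0, 0.11),
)


@dataclass
class TitrationSeries:
    """Ordered (equivalents, slice) pairs sharing one frequency axis."""

    points: list[tuple[float, Spectrum1D]]
    P0: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        eqs = [e for e, _ in self.points]
        if any(e < 0 for e in eqs):
            raise ValueError("equivalents must be >= 0")
        if any(b <= a for a, b in zip(eqs, eqs[1:])):
            raise ValueError("equivalents must be strictly increasing")
        if self.points:
            axis = self.points[0][1].frequency
            for _, s in self.points[1:]:
                if s.frequency.shape != axis.shape or not np.allclose(
                    s.frequency, axis, rtol=0, atol=1e-9
                ):
                    raise ValueError("all slices must share one frequency axis")

    @property
    def equivalents(self) -> list[float]:
        return [e for e, _ in self.points]

    @property
    def slices(self) -> list[Spectrum1D]:
        return [s for _, s in self.points]

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


@dataclass(frozen=True)
class ResidueShifts:
    """Free/bound amide shifts of one residue (ppm)."""

    residue: str
    dH_free: float = float("nan")
    dN_free: float = float("nan")
    dH_bound: float = float("nan")
    dN_bound: float = float("nan")
    assigned_free: bool = True
    assigned_bound: bool = True

    def __post_init__(self) -> None:
        if self.assigned_free and not (
            math.isfinite(self.dH_free) and math.isfinite(self.dN_free)
        ):
            raise ValueError(f"{self.residue}: free shifts must be finite when assigned")
        if self.assigned_bound and not (
            math.isfinite(self.dH_bound) and math.isfinite(self.dN_bound)
        ):
            raise ValueError(f"{self.residue}: bound shifts must be finite when assigned")


@dataclass(frozen=True)
class CSPRecord:
    residue: str
    csp: float
    bin: str

    def __post_init__(self) -> None:
        if self.csp < 0:
            raise ValueError("CSP must be >= 0")


def default_equivalents_grid() -> list[float]:
    """The experimental titration grid: 0.1 steps to 1.5, 0.5 steps to 5.5."""
    fine = [round(0.1 * i, 10) for i in range(16)]  # 0.0 .. 1.5
    coarse = [round(2.0 + 0.5 * i, 10) for i in range(8)]  # 2.0 .. 5.5
    return fine + coarse


def simulate_titration(
    scheme: ExchangeScheme,
    spin: SpinParameters,
    P0: float,
    grid: list[float] | None = None,
    acq: AcquisitionSettings | None = None,
) -> TitrationSeries:
    """Simulate one slice per equivalents value (L0 = eq * P0)."""
    if grid is None:
        grid = default_equivalents_grid()
    if acq is None:
        acq = AcquisitionSettings()
    points = [
        (eq, simulate_slice(scheme, spin, MixComposition(P0=P0, L0=eq * P0), acq))
        for eq in grid
    ]
    return TitrationSeries(
        points=points,
        P0=P0,
        metadata={
            "k1_on_per_M_s": scheme.k1_on,
            "k1_off_per_s": scheme.k1_off,
            "k2_per_s": scheme.k2,
            "k2_prime_per_s": scheme.k2_prime,
            "omega_P_hz": spin.omega_P,
            "omega_PL_hz": spin.omega_PL,
            "R2_per_s": spin.R2,
            "echo_time_s": spin.echo_time,
            "spectral_width_hz": acq.spectral_width,
            "n_points": acq.n_points,
            "zero_fill_factor": acq.zero_fill_factor,
            "apodization": acq.apodization,
        },
    )


def csp(rs: ResidueShifts, nitrogen_scaling: str = "quarter-shift") -> float:
    """Combined 1H/15N chemical shift perturbation (ppm).

    ``nitrogen_scaling`` selects where the nitrogen weight sits:
    "quarter-shift" squares the scaled difference, sqrt(dH^2 + (dN/4)^2)
    (the default); "quarter-square" scales the squared difference,
    sqrt(dH^2 + dN^2/4).  Unassigned residues (in either state) give 0.
    """
    if not (rs.assigned_free and rs.assigned_bound):
        return 0.0
    dh = rs.dH_free - rs.dH_bound
    dn = rs.dN_free - rs.dN_bound
    if nitrogen_scaling == "quarter-shift":
        return math.sqrt(dh * dh + (dn / 4.0) ** 2)
    if nitrogen_scaling == "quarter-square":
        return math.sqrt(dh * dh + dn * dn / 4.0)
    raise ValueError(f"unknown nitrogen_scaling {nitrogen_scaling!r}")


def classify_csp(value: float) -> str:
    """Map a CSP value (ppm) to its structure-mapping bin.

    Bins are half-open [lower, upper), so every value >= 0 lands in
    exactly one bin and boundary values go to the upper bin.
    """
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"CSP must be finite and >= 0, got {value!r}")
    for label, lo, hi in CSP_BINS:
        if lo <= value < hi:
            return label
    raise AssertionError("unreachable: bins cover [0, inf)")


def _index_table(table: "pd.DataFrame", which: str) -> "pd.DataFrame":
    import pandas as pd  # local: keep module import light

    df = pd.DataFrame(table)
    missing = {"residue", "dH", "dN"} - set(df.columns)
    if missing:
        raise ValueError(f"{which} table missing columns {sorted(missing)}")
    if "assigned" not in df.columns:
        df = df.assign(assigned=True)
    if df["residue"].duplicated().any():
        dups = df.loc[df["residue"].duplicated(), "residue"].tolist()
        raise ValueError(f"duplicate residue ids in {which} table: {dups}")
    return df.set_index("residue")


def csp_table(free_table, bound_table, nitrogen_scaling: str = "quarter-shift") -> list[CSPRecord]:
    """Join per-state shift tables and compute one CSPRecord per residue.

    Each table is a DataFrame (or anything coercible to one) with columns
    ``residue, dH, dN`` and optional boolean ``assigned``.  One record is
    produced per residue present in either table; a residue missing from
    one table, or flagged unassigned there, gets CSP 0.
    """
    free = _index_table(free_table, "free")
    bound = _index_table(bound_table, "bound")
    order = list(free.index) + [r for r in bound.index if r not in free.index]
    records = []
    for rid in order:
        f_ok = rid in free.index and bool(free.at[rid, "assigned"])
        b_ok = rid in bound.index and bool(bound.at[rid, "assigned"])
        rs = ResidueShifts(
            residue=str(rid),
            dH_free=float(free.at[rid, "dH"]) if f_ok else float("nan"),
            dN_free=float(free.at[rid, "dN"]) if f_ok else float("nan"),
            dH_bound=float(bound.at[rid, "dH"]) if b_ok else float("nan"),
            dN_bound=float(bound.at[rid, "dN"]) if b_ok else float("nan"),
            assigned_free=f_ok,
            assigned_bound=b_ok,
        )
        value = csp(rs, nitrogen_scaling=nitrogen_scaling)
        records.append(CSPRecord(residue=str(rid), csp=value, bin=classify_csp(value)))
    return records
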