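"""Three-state exchange scheme and binding equilibrium.

The binding model is

    P + L  <=[k1_on]=[k1_off]=>  PL  <=[k2]=[k2_prime]=>  PL*

where P is the free protein, L the free peptide, PL the canonically bound
complex and PL* a bound-state conformer in which individual contacts are
transiently broken ("partially unbound") without overall dissociation.
Because PL* interconverts only with PL, the equilibrium concentrations
follow from a single quadratic in [PL]: writing A = 1 + k2/k2', mass
balance gives [P] = P0 - A[PL], [L] = L0 - A[PL], [PL*] = (k2/k2')[PL],
and detailed balance of the bimolecular step requires

    k1_off [PL] - k1_on (L0 - A[PL]) (P0 - A[PL]) = 0.

All concentrations are molar and all times seconds; "equivalents"
(L0/P0) is purely a presentation-layer quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ExchangeScheme",
    "MixComposition",
    "EquilibriumState",
    "KineticRow",
    "solve_equilibrium",
    "kd_from_rates",
    "scheme_kd",
]


@dataclass(frozen=True)
class ExchangeScheme:
    """Rate constants of the three-state binding/isomerization scheme.

    Parameters
    ----------
    k1_on : float
        Bimolecular association rate constant (M^-1 s^-1).
    k1_off : float
        Dissociation rate constant (s^-1).
    k2 : float
        Forward isomerization rate PL -> PL* (s^-1).
    k2_prime : float
        Reverse isomerization rate PL* -> PL (s^-1).
    """

    k1_on: float
    k1_off: float
    k2: float = 0.0
    k2_prime: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1_on", "k1_off", "k2", "k2_prime"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.k2 > 0 and self.k2_prime == 0:
            raise ValueError(
                "k2 > 0 with k2_prime = 0 makes PL* absorbing; "
                "the equilibrium ratio [PL*]/[PL] is undefined"
            )

    @property
    def A(self) -> float:
        """Isomerization factor A = 1 + k2/k2' (= 1 when k2 = 0)."""
        if self.k2 == 0.0:
            return 1.0
        return 1.0 + self.k2 / self.k2_prime


@dataclass(frozen=True)
class MixComposition:
    """Total protein and ligand concentrations of one titration point (M)."""

    P0: float
    L0: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.P0) and self.P0 > 0):
            raise ValueError(f"P0 must be finite and > 0, got {self.P0!r}")
        if not (math.isfinite(self.L0) and self.L0 >= 0):
            raise ValueError(f"L0 must be finite and >= 0, got {self.L0!r}")

    @property
    def equivalents(self) -> float:
        return self.L0 / self.P0


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium species concentrations (M)."""

    P: float
    PL: float
    PLstar: float
    L: float

    def __post_init__(self) -> None:
        for name in ("P", "PL", "PLstar", "L"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def bound_fraction(self) -> float:
        """Fraction of protein in either bound state."""
        total = self.P + self.PL + self.PLstar
        return (self.PL + self.PLstar) / total


@dataclass(frozen=True)
class KineticRow:
    """One peptide's measured association/dissociation rates."""

    peptide: str
    k_on: float
    k_on_err: float = 0.0
    k_off: float = 0.0
    k_off_err: float = 0.0

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError(f"k_on must be > 0, got {self.k_on!r}")
        if self.k_off < 0:
            raise ValueError(f"k_off must be >= 0, got {self.k_off!r}")

    @property
    def kd(self) -> float:
        return kd_from_rates(self.k_on, self.k_off)


def kd_from_rates(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant K_d = k_off / k_on (M)."""
    if k_on <= 0:
        raise ValueError(f"k_on must be > 0, got {k_on!r}")
    if k_off < 0:
        raise ValueError(f"k_off must be >= 0, got {k_off!r}")
    return k_off / k_on


def scheme_kd(scheme: ExchangeScheme) -> float:
    """K_d of the bimolecular step of a scheme (k1_off / k1_on)."""
    return kd_from_rates(scheme.k1_on, scheme.k1_off)


def solve_equilibrium(scheme: ExchangeScheme, mix: MixComposition) -> EquilibriumState:
    """Solve the three-state binding equilibrium for one titration point.

    Expanding the equilibrium condition in x = [PL] gives

        k1_on A^2 x^2 - (k1_off + k1_on A (P0 + L0)) x + k1_on P0 L0 = 0

    whose smaller root is the unique physical solution (the larger root
    always violates A x <= min(P0, L0)).  The root is evaluated with the
    Citardauq form x = 2c / (-b + sqrt(b^2 - 4ac)), which stays accurate
    when k1_off << k1_on * P0 — the femtomolar-Kd regime, where the naive
    formula cancels catastrophically.
    """
    A = scheme.A
    P0, L0 = mix.P0, mix.L0
    if L0 == 0.0 or scheme.k1_on == 0.0:
        pl = 0.0
    else:
        a = scheme.k1_on * A * A
        b = -(scheme.k1_off + scheme.k1_on * A * (P0 + L0))
        c = scheme.k1_on * P0 * L0
        disc = b * b - 4.0 * a * c
        # disc >= 0 always for physical inputs; guard rounding
        pl = 2.0 * c / (-b + math.sqrt(max(disc, 0.0)))
    plstar = (scheme.k2 / scheme.k2_prime) * pl if scheme.k2 > 0 else 0.0
    p = P0 - A * pl
    l_free = L0 - A * pl
    # absorb tiny negative round-off in the stoichiometric limit
    tol = 1e-15 * P0
    if -tol <= p < 0.0:
        p = 0.0
    if -tol <= l_free < 0.0:
        l_free = 0.0
    return EquilibriumState(P=p, PL=pl, PLstar=plstar, L=l_free)
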