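"""Synthetic titration fixtures with known ground truth.

Emulates the experimental 1D titration traces: exchange-broadened
Lorentzian-like peaks over the molar-equivalents grid with additive,
frequency-point-independent Gaussian noise scaled to the series' global
maximum.  Two presets reproduce the published simulation parameter sets
for the two regimes studied:

* preset "A" — the nanomolar complex (Kd = 300 nM): k1_on = 1e9
  M^-1 s^-1, k1_off = 300 s^-1, k2 = 30 s^-1, k2' = 700 s^-1,
  delta-omega = 294 Hz; fast/intermediate exchange, one shifting peak.
* preset "B" — the femtomolar complex (Kd = 484 fM): k1_on = 6.2e8,
  k1_off = 3e-4, k2 = 30, k2' = 100, delta-omega = 246 Hz; slow
  exchange, a bound peak that builds up to 1.0 equivalents.

Both use P0 = 250 uM and an 11 ms spin echo.  The free-protein offset is
anchored at 0 Hz: only the shift difference is physically constrained,
absolute offsets are irrelevant to the exchange problem.

Noise is injected in the frequency domain by default (processed
frequency-domain traces are what gets compared); a complex time-domain
noise option exists for realism but is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import ExchangeScheme, scheme_kd
from .lineshape import AcquisitionSettings, SpinParameters, Spectrum1D
from .titration import (
    CSP_BINS,
    CSPRecord,
    TitrationSeries,
    classify_csp,
    default_equivalents_grid,
    simulate_titration,
)

__all__ = ["GroundTruth", "regime_presets", "generate_series", "generate_shift_tables"]


@dataclass(frozen=True)
class GroundTruth:
    """Complete parameterization of one synthetic titration series."""

    scheme: ExchangeScheme
    spin: SpinParameters
    P0: float
    grid: tuple[float, ...]
    acq: AcquisitionSettings
    noise_sigma: float = 0.0  # fraction of the series' global max height
    noise_domain: str = "frequency"  # or "time"
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_domain not in ("frequency", "time"):
            raise ValueError(f"unknown noise_domain {self.noise_domain!r}")

    @property
    def kd(self) -> float:
        return scheme_kd(self.scheme)

    def with_(self, **kwargs) -> "GroundTruth":
        return replace(self, **kwargs)


def regime_presets(
    acq: AcquisitionSettings | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> dict[str, GroundTruth]:
    """Ground-truth templates for the two published simulation regimes."""
    if acq is None:
        acq = AcquisitionSettings()
    grid = tuple(default_equivalents_grid())
    common = dict(P0=250e-6, grid=grid, acq=acq, noise_sigma=noise_sigma, seed=seed)
    return {
        "A": GroundTruth(
            scheme=ExchangeScheme(k1_on=1e9, k1_off=300.0, k2=30.0, k2_prime=700.0),
            spin=SpinParameters(omega_P=0.0, omega_PL=294.0, R2=60.0, echo_time=0.011),
            label="A",
            **common,
        ),
        "B": GroundTruth(
            scheme=ExchangeScheme(k1_on=6.2e8, k1_off=3e-4, k2=30.0, k2_prime=100.0),
            spin=SpinParameters(omega_P=0.0, omega_PL=246.0, R2=60.0, echo_time=0.011),
            label="B",
            **common,
        ),
    }


def generate_series(truth: GroundTruth) -> tuple[TitrationSeries, GroundTruth]:
    """Simulate the noiseless series, then add seeded Gaussian noise.

    Frequency-domain noise (default) is additive i.i.d. Gaussian per
    frequency point with standard deviation noise_sigma times the
    global maximum intensity of the noiseless series.
    """
    series = simulate_titration(
        truth.scheme, truth.spin, truth.P0, list(truth.grid), truth.acq
    )
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        if truth.noise_domain == "time":
            # re-simulate with complex noise on each FID
            from .kinetics import MixComposition, solve_equilibrium
            from .lineshape import (
                apply_spin_echo,
                evolution_matrix,
                initial_magnetization,
                propagate_fid,
                spectrum_from_fid,
            )

            noisy_points = []
            for eq, _ in series:
                mix = MixComposition(P0=truth.P0, L0=eq * truth.P0)
                eqst = solve_equilibrium(truth.scheme, mix)
                G = evolution_matrix(truth.scheme, truth.spin, eqst.L)
                m0 = initial_magnetization(eqst)
                fid = propagate_fid(
                    G, apply_spin_echo(G, m0, truth.spin.echo_time), truth.acq
                )
                sigma_t = truth.noise_sigma * np.abs(fid).max()
                fid = fid + sigma_t * (
                    rng.standard_normal(len(fid)) + 1j * rng.standard_normal(len(fid))
                )
                spec = spectrum_from_fid(fid, truth.acq)
                spec.metadata.update({"equivalents": eq, "noise_sigma": truth.noise_sigma})
                noisy_points.append((eq, spec))
            series = TitrationSeries(noisy_points, P0=truth.P0, metadata=dict(series.metadata))
        else:
            global_max = max(s.intensity.max() for s in series.slices)
            sigma = truth.noise_sigma * global_max
            for _, spec in series:
                spec.intensity = spec.intensity + sigma * rng.standard_normal(
                    len(spec.intensity)
                )
                spec.metadata["noise_sigma"] = truth.noise_sigma
    series.metadata.update(
        {"noise_sigma": truth.noise_sigma, "seed": truth.seed, "label": truth.label}
    )
    return series, truth


def generate_shift_tables(
    n_residues: int | None = None,
    bin_design: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[CSPRecord]]:
    """Draw free/bound shift tables whose CSPs land in requested bins.

    ``bin_design`` maps bin label -> residue count; perturbations are
    drawn strictly inside each bin's CSP interval and split randomly
    between the 1H and (4x-scaled) 15N dimensions.  Returns the two
    tables plus the expected classification.
    """
    if bin_design is None:
        bin_design = {"none": n_residues or 10}
    bins = {label: (lo, hi) for label, lo, hi in CSP_BINS}
    for label, count in bin_design.items():
        if label not in bins:
            raise ValueError(f"unknown bin {label!r}")
        if count < 0:
            raise ValueError(f"negative count for bin {label!r}")
    total = sum(bin_design.values())
    if n_residues is not None and n_residues != total:
        raise ValueError(f"n_residues={n_residues} inconsistent with bin_design total {total}")

    rng = np.random.default_rng(seed)
    rows_free, rows_bound, expected = [], [], []
    i = 0
    for label, count in bin_design.items():
        lo, hi = bins[label]
        hi_eff = hi if math.isfinite(hi) else max(2.0 * lo, 1.5)
        for _ in range(count):
            i += 1
            rid = f"R{i}"
            # margin keeps draws strictly inside the half-open bin
            width = hi_eff - lo
            target = lo + width * rng.uniform(0.05, 0.95)
            theta = rng.uniform(0.0, math.pi / 2.0)
            dh = target * math.cos(theta)
            dn = 4.0 * target * math.sin(theta)
            h_free, n_free = rng.uniform(6.5, 10.5), rng.uniform(105.0, 130.0)
            sh, sn = rng.choice([-1.0, 1.0]), rng.choice([-1.0, 1.0])
            rows_free.append({"residue": rid, "dH": h_free, "dN": n_free, "assigned": True})
            rows_bound.append(
                {"residue": rid, "dH": h_free + sh * dh, "dN": n_free + sn * dn, "assigned": True}
            )
            expected.append(CSPRecord(residue=rid, csp=target, bin=classify_csp(target)))
    free = pd.DataFrame(rows_free, columns=["residue", "dH", "dN", "assigned"])
    bound = pd.DataFrame(rows_bound, columns=["residue", "dH", "dN", "assigned"])
    return free, bound, expected
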