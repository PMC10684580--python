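# mcshape

Bloch–McConnell line-shape simulation and fitting for NMR titrations of
peptide–repeat-protein complexes.

## The problem

Designed Armadillo repeat proteins (dArmRPs) bind Lys–Arg repeat
peptides ((KR)_n) with affinities reaching the femtomolar range, yet
their HSQC titration spectra show bound-state signals far broader than
transverse relaxation alone can explain.  At a K_d of ~10⁻¹³ M the
off-rate is ~10⁻⁴ s⁻¹ — complete unbinding is orders of magnitude too
slow to broaden anything.  The observed widths require a second,
millisecond-scale exchange process *within* the bound state: transient
breakage of individual contacts without overall dissociation.

`mcshape` implements the quantitative machinery to test that
hypothesis: a three-state exchange model, exact line-shape simulation,
titration-series generation with known ground truth, least-squares
model comparison (two-state vs three-state), and the supporting
equilibrium, kinetics and chemical-shift-perturbation computations.

## The model

Binding and bound-state isomerization follow

```
P + L  ⇌(k₁,on / k₁,off)  PL  ⇌(k₂ / k₂′)  PL*
```

where PL* is a partially (transiently) unbound conformer that resonates
at the free-protein shift Ω_P.  Transverse magnetization of the three
protein states evolves under the coupled Bloch–McConnell equations

```
dM_P/dt   = (−i2πΩ_P  − R₂ − k₁,on[L]) M_P + k₁,off M_PL
dM_PL/dt  = (−i2πΩ_PL − R₂ − k₁,off − k₂) M_PL + k₁,on[L] M_P + k₂′ M_PL*
dM_PL*/dt = (−i2πΩ_P  − R₂ − k₂′) M_PL* + k₂ M_PL
```

with a shared relaxation rate R₂ and the free-ligand concentration [L]
fixed at its equilibrium value.  Writing A = 1 + k₂/k₂′, the
equilibrium [PL] is the physical root of

```
k₁,off[PL] − ([L₀] − A[PL])([P₀] − A[PL]) k₁,on = 0
```

and [P] = P₀ − A[PL], [L] = L₀ − A[PL], [PL*] = (k₂/k₂′)[PL].
Simulation starts from magnetization proportional to the equilibrium
populations, evolves through an 11 ms spin echo (ideal 180° pulse), is
sampled at dwell-time multiples via the exact matrix-exponential
solution, apodized with a shifted cosine bell, zero-filled and
Fourier-transformed.  Chemical shift perturbations are
√(ΔδH² + (ΔδN/4)²) and binned at 1.0 / 0.5 / 0.25 / 0.11 ppm.

## Worked example

```python
from mcshape import (AcquisitionSettings, FitConfig, regime_presets,
                     generate_series, model_comparison)

acq = AcquisitionSettings(n_points=1024)
truth = regime_presets(acq=acq)["A"]          # Kd = 300 nM regime
truth = truth.with_(grid=(0.0, 0.3, 0.6, 0.9, 1.1, 1.3),
                    noise_sigma=0.015, seed=1)
series, _ = generate_series(truth)

cfg = FitConfig(
    free={"k2": (1.0, 1e4), "k2_prime": (10.0, 1e5),
          "R2": (5.0, 300.0), "scale": (0.5, 2.0)},
    fixed={"k1_on": 1e9, "omega_P": 0.0, "omega_PL": 294.0},
    kd_constraint=300e-9, n_starts=3, seed=1, window=(-150.0, 450.0),
)
report = model_comparison(series, acq, cfg)
print(report["objective_two_state"], report["objective_three_state"])
print(report["three_state"].params["k2"], report["three_state"].params["k2_prime"])
```

prints (seed 1)

```
1.3839914270317761 0.4162932111892915
29.863361753540758 627.3842420977542
```

— the two-state restriction (k₂ = 0) fits ~3.3× worse than the full
model, and the fit recovers the generating isomerization rates
k₂ = 30 s⁻¹, k₂′ = 700 s⁻¹ from the noisy series.  The same comparison
for the femtomolar preset gives an objective ratio of ~8.3.

The numbered scripts under `analysis/` run the full story — the
(KR)₅₋₇ dissociation-constant table, simulated titrations of both
exchange regimes with peak trajectories, the two- vs three-state model
comparison, and CSP bin mapping — writing tables to `results/`.

A `mcshape` command-line tool (subcommands `simulate`, `titrate`,
`fit`, `compare`, `csp`, `synth`) covers the same pipeline for
file-based workflows; see `mcshape --help`.

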