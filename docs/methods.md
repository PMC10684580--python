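# Methods

## Model

The package treats one observed amide of a repeat protein P titrated
with a peptide ligand L under the three-state scheme

    P + L  ⇌(k1_on / k1_off)  PL  ⇌(k2 / k2′)  PL*

PL is the canonically bound complex; PL* is a bound-state conformer in
which individual protein–peptide contacts are transiently broken while
the complex stays associated.  Its chemical shift is defined equal to
the free-protein shift Ω_P (the contact-broken amide samples a
free-like environment), and all three states share one transverse
relaxation rate R2.  These two assumptions keep the model at four rate
constants, two offsets and one relaxation rate; they are assumptions,
not fits — releasing them would add parameters that 1D slices cannot
determine.

### Equilibrium

Because PL* communicates only with PL, detailed balance fixes
[PL*] = (k2/k2′)[PL]; with A = 1 + k2/k2′ the mass balances close and
[PL] solves

    k1_off·[PL] − ([L0] − A[PL])([P0] − A[PL])·k1_on = 0,

a quadratic k1_on A² x² − (k1_off + k1_on A(P0+L0)) x + k1_on P0 L0 = 0.
The smaller root is the unique physical one (the larger always violates
A·[PL] ≤ min(P0, L0)).  It is evaluated in the Citardauq form
x = 2c/(−b + √(b²−4ac)): with femtomolar dissociation constants
k1_off ≪ k1_on·P0 and the conventional formula cancels
catastrophically.  Round-off below 10⁻¹⁵·P0 in the stoichiometric limit
is clamped to zero.  Internal units are molar and seconds throughout;
"equivalents" = L0/P0 exists only at the presentation layer.

### Magnetization evolution

Transverse magnetization M = (M_P, M_PL, M_PL*) evolves under
dM/dt = G·M with

    G = [ −i2πΩ_P − R2 − k1_on[L]      k1_off                0
          k1_on[L]        −i2πΩ_PL − R2 − k1_off − k2        k2′
          0                            k2        −i2πΩ_P − R2 − k2′ ]

Offsets are entered in Hz (the natural unit of the figures and of peak
readout) and converted to angular frequency inside the generator.  The
real parts of every column sum to −R2: exchange conserves total
magnetization, relaxation does not — this is asserted in tests.  The
free-ligand concentration is frozen at its equilibrium value during the
FID (pseudo-first-order treatment); ligand magnetization is never
tracked, since the experiment observes protein amides.  Detection
weighs all three states equally — they carry the same amide.

Propagation uses the exact solution of the linear time-invariant
system: eigendecomposition of G sampled at dwell-time multiples.  A
generic ODE stepper would only approximate the same trajectory slower;
the accuracy contract (agreement with a fine-step explicit RK4
integrator to 1e-8 of the maximum amplitude) is what the tests pin.

### Spin echo

Acquisition is preceded by a spin echo of total duration 11 ms
(default), emulating signal losses during the INEPT periods of the
HSQC: M(τ) = U·conj(U·M0) with U = exp(G·τ/2) and an ideal,
instantaneous 180° pulse (element-wise complex conjugation).  Without
exchange this attenuates by exactly exp(−R2·τ) with zero net phase;
exchange between states of unequal shift defeats the refocusing and
attenuates further.  Pulse imperfections are out of scope.

### Processing

The detected FID s(t) = M_P + M_PL + M_PL* is apodized with a
90°-shifted sine (cosine) bell over the acquired length, its first
point halved (standard discrete-transform baseline correction),
zero-filled, and Fourier-transformed so that a species at offset +Ω Hz
appears at +Ω Hz.  The real (absorption) part is compared by default;
magnitude mode is available.  Exact vendor window parameters for the
original spectra are not published, so the window is configurable; the
default acquisition (spectral width 4000 Hz, 2048 complex points,
zero-fill 2) resolves the line widths of both simulation regimes and is
likewise configurable.  Peak readout interpolates a parabola through
the three points around the discrete maximum and takes FWHM from linear
interpolation of the half-height crossings; no baseline correction is
applied, so callers must window sensibly.

## Parameters that matter

| parameter | unit | preset A | preset B | meaning |
|---|---|---|---|---|
| k1_on  | M⁻¹s⁻¹ | 1e9   | 6.2e8 | association rate |
| k1_off | s⁻¹    | 300   | 3e-4  | dissociation rate (Kd = k1_off/k1_on: 300 nM / 484 fM) |
| k2     | s⁻¹    | 30    | 30    | contact breakage PL→PL* |
| k2′    | s⁻¹    | 700   | 100   | contact reformation PL*→PL |
| Δω     | Hz     | 294   | 246   | bound-minus-free shift difference |
| R2     | s⁻¹    | 60    | 60    | shared transverse relaxation rate |
| echo   | s      | 0.011 | 0.011 | pre-acquisition spin echo |
| P0     | M      | 250e-6 | 250e-6 | total protein concentration |

Presets A and B are the two published simulation regimes
(fast/intermediate nanomolar and slow femtomolar exchange).  Ω_P is
anchored at 0 Hz: only Δω is physically constrained, absolute offsets
are irrelevant to the exchange problem.  R2 = 60 s⁻¹ is the package's
own choice of a realistic amide R2 for a ~20–30 kDa protein at
600–700 MHz; it is not a published value and every preset field is
overridable.  The titration grid is the experimental protocol: 0.1
molar-equivalent steps to 1.5, then 0.5 steps to 5.5 (24 points).

## Synthetic data

The generator simulates the noiseless series and adds i.i.d. Gaussian
noise per frequency point with standard deviation noise_sigma times the
series' global maximum, seeded; a complex time-domain noise option
exists but is off by default, since processed frequency-domain traces
are what get compared.  What it emulates: exchange-broadened 1D slices
over a titration, with the correct equilibrium populations, echo
losses and processing.  What it does not: 2D peak overlap, ¹⁵N-dimension
structure, baseline roll, solvent artifacts, temperature drift, or
correlated noise.  Passing recovery tests therefore show the inference
machinery is sound under the stated noise model — not that every real
spectrum is as kind.  Shift-table fixtures draw ΔδH/ΔδN pairs landing
strictly inside requested CSP bins (5% margins) so classifier tests
have exact expected counts.

## Fitting

The by-eye comparison of simulated and measured traces is replaced by
an explicit least-squares objective: simulated and observed real
spectra are max-normalized and pointwise squared differences summed
over an analysis window and over slices.  Normalization uses one
constant per series by default, preserving the relative intensity
buildup across titration points.  The per-slice alternative is
available but discouraged: near coalescence the signal can drop below
the noise, and normalizing such a slice to unit height lets pure noise
dominate the fit.  A feature objective (squared peak-position and FWHM
errors in axis-step units) mirrors fitting "position and line width"
directly and is selectable.

Rate constants span decades, so free rates are fitted as log10 values;
multi-start initial guesses are drawn log-uniformly (rates) or
uniformly (others) within bounds from a seeded generator, with the
first start at the (geometric) midpoint.  Bounded least squares runs
via lmfit's trust-region-reflective backend; the best of all converged
starts wins, and everything is deterministic given the seed.  A K_d
constraint ties k1_off = K_d·k1_on, reflecting that the binding
constant is usually known independently (stopped-flow, fluorescence
polarization) while the line shape informs the isomerization step.

Identifiability is reported, never silently resolved.  At the optimum a
finite-difference Hessian of the objective is taken in the internal
coordinates (relative steps of 1e-3); eigendirections with curvature
below 1e-6 of the largest eigenvalue are reported as flat modes with
their loadings, and any free parameter loading above 0.4 on a flat
mode is flagged.  On saturated-only data with the bound-state shift
free this reproduces the experimentally known ambiguity: a flat
direction dominated by Ω_PL with the isomerization rates riding along.

Model comparison refits with k2 = k2′ = 0 under shared settings and
reports both objectives and their ratio; the two-state model is nested
in the three-state one, so the ratio is ≥ 1 up to optimizer tolerance.

## Numerical and design choices

- CSP formula: the printed form is ambiguous between ((ΔδN)/4)² and
  (ΔδN)²/4; the quarter-shift reading ((ΔδN)/4)² is the default, the
  alternative sits behind `nitrogen_scaling="quarter-square"`.  The
  denominator 4 (not the more common 5) is adopted as printed.
- CSP bins: the caption's strict inequalities leave boundary values
  unassigned; half-open-upward bins [1,∞), [0.5,1), [0.25,0.5),
  [0.11,0.25), [0,0.11) are imposed so classification is total.
- Unassigned residues get CSP 0 (as in the source protocol) but records
  keep the assignment flags, so "zero" and "unknown" stay separable.
- Signal conservation: the integral of the (real) spectrum equals the
  conserved initial magnetization and is independent of exchange rates
  at fixed R2; the magnitude-spectrum integral is *not* conserved (a
  magnitude Lorentzian has 1/|f| tails whose finite-window integral
  depends on the width), so the conservation test asserts the real
  form.
- Text spectra are written at full float precision (%.17g) so a disk
  round-trip is numerically exact.
- The published kinetic table's (KR)₄ row prints an off-rate
  inconsistent with its own K_d (a typesetting artifact); it is
  excluded from the shipped tables rather than silently corrected.

## Problem sizes used by tests and the acceptance script

Fitting tests use 1024-point acquisitions, 6-slice sub-grids of the
titration (0–1.3 equivalents), 3 starts and 20 noise seeds per regime
at noise_sigma = 0.015 — enough to separate the models cleanly (the
two-state/three-state objective ratios come out ~3 and ~8) while the
whole suite stays interactive.  Oracle-equivalence checks use 50
random parameter draws at 256–1024 points; line-width metrology uses
unapodized 4096-point/4× zero-filled spectra.

## Known limitations

- 1D only: Δω is a scalar offset of the observed dimension; no 2D HSQC
  simulation or ¹⁵N-dimension modeling.
- One site per spectrum: multi-peak slices must be windowed per peak.
- No sequential two-peptide binding model (short peptide on long
  protein); no Bayesian posterior — uncertainty reporting is limited to
  flat-direction diagnostics and multi-seed spread.
- The echo treats the 180° pulse as ideal; off-resonance and B1 effects
  are ignored.
- No vendor binary formats; spectra enter as two-column text.
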