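# Methods

## Model

The hydroxy torsion is treated as a one-dimensional hindered rotor: a
single periodic coordinate τ (the HCOH-type dihedral, degrees externally,
radians internally) moving in a 360°-periodic potential V(τ) with a
constant effective inertia. The stationary Schrödinger equation is

    −F χ″(τ) + V(τ) χ(τ) = E χ(τ),    χ(τ + 2π) = χ(τ),

with all energies in cm⁻¹ (E = hc ν̃) and the kinetic coefficient
F = ħ²/(2 I hc) = 16.85763 / I cm⁻¹ for I in amu·Å². The constant follows
from the rotational-constant identity B = h/(8π²cI) with CODATA constants;
the same identity gives the kJ/mol → cm⁻¹ conversion 83.59347 used by the
scan reader.

Assumptions inherited by everything downstream:

* the torsion separates adiabatically from all other modes (stretch
  excitation enters only through a modified potential and inertia);
* I does not depend on τ (for real hydroxy rotors the variation between
  stationary points is at the percent level; a τ-dependent inertia is out
  of scope);
* transition intensities are discussed only at the Franck–Condon level —
  the squared overlap of torsional wavefunctions between stretch
  manifolds. The transition-dipole dependence on τ is deliberately not
  modelled, so FCFs underestimate nominally "forbidden" satellites when
  that dependence is antisymmetric.

## Potential representation and surgery

A potential is a truncated real Fourier series
a₀ + Σₖ (aₖ cos kτ + bₖ sin kτ) plus optional additive overlays. The energy
zero is the minimum of the smooth part on a 0.1° grid. Two overlay kinds
exist and compose at evaluation time without touching the Fourier
coefficients:

* **rectangular barrier** — a top-hat of given center/width/height, used
  for artificial localization;
* **piecewise-linear correction** — produced by anchor rescaling: when the
  stationary-point energies are replaced by refined values, the correction
  c(τ) is interpolated linearly in τ between consecutive anchors, so every
  anchor lands exactly on its corrected energy while the connecting
  segments keep their shape. An additive (rather than multiplicative)
  correction was chosen because it is shape-preserving, exact at the
  anchors, continuous, and well defined even where the original segment
  spans zero. Stretch-excited potentials reuse this machinery with
  corrected = current + harmonic stretch wavenumber per stationary point.

Symmetrization about a transition state at τ_ts maps the series into the
frame φ = τ − τ_ts, where the mirror average keeps exactly the cos(kφ)
components; it is performed in coefficient space and is therefore exact
and idempotent. It requires a pure-Fourier potential (overlays would need
a refit first, `PeriodicPotential.to_fourier`).

Stationary points are located by sign-change bracketing of the analytic
Fourier derivative on a 0.05° grid plus Brent refinement (≤ 1e-4°),
classified by the second derivative; roots closer than 0.5° are merged as
flat-top artifacts. Overlays are excluded: barriers are discontinuous and
anchor corrections have kinks at the anchors by construction.

## Eigensolver

The production solver expands in the orthonormal real free-rotor basis
{1/√2π, cos mτ/√π, sin mτ/√π}, m ≤ M (cos block before sin, which also
fixes the tie-break for degenerate free-rotor pairs), with potential
matrix elements by trapezoidal quadrature on ≥ 8M uniform points —
spectrally accurate for smooth periodic integrands. The returned
eigenpairs come from a basis-doubled solve; a result is flagged
non-converged when doubling moved any requested eigenvalue by more than
1e-4 cm⁻¹. Wavefunction phase is fixed by making the amplitude at the
largest-|χ| grid point positive.

An independent cross-check solver builds the periodic three-point
Laplacian on an n-point grid (default 4096) and extracts the lowest states
with shift-inverted sparse diagonalization. Its error is O(h²); tests
verify the Richardson factor-of-4 decay. Plane-wave and grid routes agree
to < 1e-3 cm⁻¹ on the lowest four states across randomized two-well
fixtures (grid route at n = 8192, where its own discretization error is
a few 1e-4 cm⁻¹ for light rotors).

**Discontinuous overlays.** A spectral basis handles the towering top-hat
wall poorly: Gibbs truncation limits lowest-pair gaps to ~1e-5–1e-3 cm⁻¹
even at M = 400, while the dense-grid solver, whose potential term is
diagonal, resolves the same gap to ~1e-12. `localize_and_decompose`
therefore solves the *localized* eigenproblem on the grid by default
(`localized_method="grid"`, n = 8192), anchoring one grid point at the
wall center: an anchored grid keeps a mirror-symmetric problem exactly
reflection-symmetric, so symmetric near-degeneracies are not split by
discretization error. The unmodified (smooth) potential is always solved
spectrally.

## Artificial localization and the two-level decomposition

T is the lowest-pair gap of the potential as given. δ is the lowest-pair
gap after inserting the wall (default 1° wide, 10⁶ cm⁻¹ tall) at the
transition state, signed positive when the localized ground state
occupies the reference well — the well containing the global minimum
(tie: smaller angle). Δ = √(T² − δ²). When the measured |δ| exceeds T
(possible, because the two wells carry different local zero-point
energies), Δ is reported as NaN with a diagnostic instead of raising: the
two-level relation is only perturbative.

The wall suppresses tunneling by roughly exp(−w·√(V_wall/F)) (WKB through
the rectangle). This scaling matters for interpreting δ: for a light
hydroxy rotor (I ≈ 0.8 amu·Å², F ≈ 21 cm⁻¹) the 1°/10⁶ wall leaves a
residual tunneling gap of order 0.01 cm⁻¹ — negligible at the 0.1 cm⁻¹
precision at which splittings are quoted, but not at tighter tolerances.
Tests that check the exact-degeneracy limit of a symmetrized potential
(δ → 0) therefore push the suppression into the fully classical regime
(3° width, 10⁷ cm⁻¹), and the sub-1e-3 cm⁻¹ suppression checks use a
methyl-like inertia (I = 3.2 amu·Å²), where the WKB exponent is large.

## Level schemes, isotope models, deviation factors

Combination differences sort the four bands descending (b₁…b₄) and assign
them (u1←l0, l1←l0, u1←u0, l1←u0), valid when the ground splitting exceeds
the excited one; an `excited_larger` override swaps the middle bands. The
two redundant estimates of each splitting are averaged and their defect
exposed as `residual` (warning above 2 cm⁻¹, about twice a typical ±1 cm⁻¹
calibration accuracy); the center of gravity is the plain four-band mean.
Calibration uncertainty is reported as metadata only, not propagated into
formal error bars.

The Morse ratio rule uses the standard isotope scaling ωₑ → √r·ωₑ,
ωₑxₑ → r·ωₑxₑ (r = μ₀/μᵢ), giving
ν̃ᵢ/ν̃₀ = (√r·ωₑ − r·2ωₑxₑ)/(ωₑ − 2ωₑxₑ); the harmonic limit is √r. With
r = 1/1.8868 and 2ωₑxₑ = 180 cm⁻¹ the ratio decreases slowly with ωₑ
(0.7379 at 3800 cm⁻¹ to 0.7377 at 3870 cm⁻¹); a fixed 0.73778 is exposed
for axis alignment between OH and OD spectra. The direct H→D splitting
correlation is a log₁₀–log₁₀ affine map with user-supplied coefficients
(a weighted least-squares fitter with optional zero intercept is
provided; no training data are bundled).

The mean symmetric deviation factor is exp of the mean |ln(exp/calc)|;
the absolute value makes over- and underestimation count equally, which
is the sense in which a value of 1.31 means "a factor of 1.31 off in
either direction". It is symmetric under exchanging experiment and
calculation and invariant under common rescaling.

## Synthetic fixture generator

`synth_double_well(barrier, asymmetry, well_separation, n_background)`
emulates the landscape of interest — two near-degenerate gauche wells
across a low transition state, with a much higher trans-region hump — as
a closed-form finite Fourier series

    V = B·u² + 2B·((1 − cos τ)/2)ⁿ + λ·sin τ,
    u = (cos τ − cos(s/2)) / (1 − cos(s/2)),

whose wells sit near ±s/2 and whose low barrier top is near 0°. λ is
solved by bracketing so the two well minima differ by exactly the
requested asymmetry; the generator then records its own stationary points
(located to ~1e-6°) as ground truth for tests. Defaults used throughout
the suite: well separation 104°, barriers 80–400 cm⁻¹, asymmetries up to
tens of cm⁻¹, inertia 0.6–3.5 amu·Å² — the regime of secondary-alcohol
hydroxy torsions and their heavier cousins. What the generator does *not*
emulate: multi-minimum fine structure, τ-dependent inertia, and coupling
to frame modes; passing tests therefore validate the numerics and the
analysis chain, not the quality of any particular electronic-structure
potential.

## Numerical choices and limitations

* Default Fourier order for scan ingestion is 12 (1° scans of C₁
  molecules need more than threefold terms); fits below 2·order+1 samples
  are rejected as underdetermined.
* Eigen-convergence flag threshold 1e-4 cm⁻¹; quadrature grid ≥ 8 points
  per basis function and ≥ 8 per degree when barriers are present.
* Stationary-point derivative tolerance 1e-8 cm⁻¹/° with 0.5° merging.
* FCF row-completeness holds only over the computed subspace; tests use
  24 upper states.
* The two-level T = √(Δ² + δ²) is validated to 5 % in the
  tunneling-dominated regime; outside it the relation degrades and the
  |δ| > T diagnostic path applies.
* The validation suite scales problem sizes (basis 60–150, grids
  4096–8192, 20-fixture sweeps) so the full run completes in seconds
  while every claimed tolerance is still met with margin.
* No randomness anywhere in the computational path; test sweeps use
  fixed-seed generators and hypothesis runs derandomized.
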