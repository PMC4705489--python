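# Methods

`ambdimer` analyses the self-association of amphotericin B (AmB) in
water at the level of a two-dimensional free-energy landscape
G(ξ, θ), where ξ is the distance between the polyene chromophores of
two monomers (Å) and θ the angle between their long principal axes
(degrees; θ < 90° parallel, θ > 90° antiparallel).  Because no
atomistic trajectories ship with the package, a calibrated parametric
reference surface plus a Brownian-dynamics umbrella sampler stand in
for the molecular-dynamics engine; every estimator in the package is
validated against exact quadrature on that surface or against
closed-form stochastic oracles.

## The reference landscape

The surface is a sum of

* an exponential repulsive wall, amplitude 6 kcal/mol at its onset
  (3.6 Å) with a 0.28 Å decay length;
* a θ-independent hydrophobic attraction: flat to 6.5 Å, then a
  Gaussian decay (width calibrated, ≈2 Å), forced to exactly zero
  beyond 20 Å by a C¹ cos² switching function (the unbound plateau
  defines G ≡ 0);
* four Gaussian bound-state basins with fixed centres
  (4.5 Å, 150°), (6.5 Å, 150°), (4.5 Å, 30°), (6.5 Å, 30°) — labels
  I, II (antiparallel) and III, IV (parallel).

exp(−βG) is defined as directly proportional to the sampled (ξ, θ)
density — the angular coordinates of the pair are already integrated
out, so no radial Jacobian appears in the landscape, in WHAM, or in
the bound-state integral.  The Jacobian is restored only where the
rate theory needs it (see the association rate below).

### Calibration

`landscape.calibrate` fits the eight free parameters (four depths, a
shared ξ width, a shared θ width, the attraction depth and its decay
width) by bounded least squares so that *exact quadrature* on the
surface reproduces the published observables: 1D minima at 4.5 and
6.5 Å with depths −5.5 kcal/mol, a 1.5 kcal/mol barrier between them,
basin populations 20/32/21/26 %, and a standard dimerization free
energy of −7.1 kcal/mol (bound boundary R = 11 Å, box volume
244 140 Å³ — a 6.25 nm cube — and V₀ = 1661 Å³).  Residuals are scaled
by per-target precisions (0.05 Å, 0.05 kcal/mol, 0.5 % …), and the
calibration fails loudly (with its residual table) if any published
tolerance is missed.  The calibrated parameter set ships as a
versioned fixture (`data/calibrated_surface.yaml`); re-running
`calibrate()` reproduces it, and perturbed optimizer starts converge
to observable-equivalent surfaces.

Two quantities the published analysis leaves unspecified are deliberate
choices here.  The θ barrier between parallel and antiparallel basins
is not printed anywhere; calibration leaves it free and it comes out
at ≈2 kcal/mol, which makes basin interconversion fast (a few ns in
the synthetic dynamics).  This is what makes per-window orientation
statistics converge at desk scale; as a consequence the package's own
flipping MFPT is *not* a reproduction of the published 200 ns value,
which is therefore exercised only through the exact identity
τ = 200 ns ↔ k = 5·10⁶ s⁻¹ and through oracle cross-validation of the
MFPT machinery.  Likewise the published k_on = 5·10⁸ M⁻¹s⁻¹ depends
on the original (unpublished) D(ξ) and is validated at the level of
the method, not the number.

## Synthetic umbrella sampling

Biased trajectories are generated by Brownian dynamics on (ξ, θ):
an Euler–Maruyama proposal per coordinate followed by a
Metropolis–Hastings correction (smart Monte Carlo / MALA), with
proposals leaving the domain (ξ ∈ [3.5, 25] Å, θ ∈ [0, 180]°)
rejected.  The Metropolis step makes the sampled stationary density
*exact* for any stable timestep — plain Euler–Maruyama left an O(dt)
density bias that was visible as a systematic shift of basin weights —
at the cost of a ≈2 % rejection rate and a correspondingly mild
slow-down of the apparent dynamics.

Defaults (the study conditions; apart from the window layout, none of
these have published values):

| parameter | default | rationale |
|---|---|---|
| windows | 17, even over 4.0–25.0 Å | published layout |
| force constant k | 2 kcal mol⁻¹ Å⁻² | σ_bias ≈ 0.55 Å ↔ 1.31 Å spacing: adjacent histograms overlap |
| D_ξ | 2 Å²/ns | conservative for small-molecule relative diffusion in water |
| D_θ | 6000 deg²/ns | same order as the published wobbling estimate (3.8·10¹² deg²/s) |
| dt | 2 ps | drift per step ≪ basin widths; MALA acceptance ≈ 98 % |
| steps/window | 1.6·10⁶ (3.2 μs, sampled every 16 steps) | ≥10³ ξ-relaxation times per window; basin-population noise ≈ 1 pp |

Each window consumes noise from its own seeded generator derived from
the base seed, so a single window regenerated in isolation is
bit-identical to its slot in the ladder, and every run is reproducible
from (config, seed) alone.

Oracle generators are kept bias-free by construction: the
Ornstein–Uhlenbeck generator uses the exact transition density (its
stationary variance and relaxation time are exact at any dt); the
wobble generator samples the polar angle with the sin θ geometric
weight; the first-passage simulator propagates replicas in lockstep
between a reflecting and an absorbing boundary.

## WHAM and reweighting

The 1D profile uses binned self-consistent WHAM (200 bins over
4–25 Å, offsets iterated to 10⁻⁷ kcal/mol, max 10⁵ iterations), with
per-window counts divided by the statistical inefficiency
g = 1 + 2Στ of the restrained coordinate (initial-positive-sequence
cutoff).  Only samples inside the histogram range enter both the
histograms and the counts — mixing out-of-range samples into the
counts (or correcting counts but not per-sample weights) biases the
window offsets, which is also why the binless 2D reweighting scales
every sample by its own window's 1/g, keeping numerator and
denominator consistent with the 1D convention.  The 2D surface
(75 × 60 bins over ξ × θ) masks unsampled bins and never imputes.
Basin populations integrate exp(−βG₂) over quadrant rectangles
meeting at ξ = 5.5 Å and θ = 90° (no published region boundaries exist), normalized over the bound region ξ < 11 Å.

## Thermodynamics

K = (V_box/V₀) · P_b/(1 − P_b), with P_b the Boltzmann weight of
ξ < R over the sampled range (trapezoid on the plateau-zeroed
profile), V₀ = 10²⁷/(N_A·c°) ≈ 1661 Å³ computed from constants, and
ΔG° = −kT ln K.  This finite-box two-molecule convention is
consistent with the angular-integrated density definition above, and
the landscape calibration absorbs it, so all downstream numbers are
convention-consistent.  No symmetry-number factor is applied for the
identical-monomer dimer.  The mass balance 2M ⇌ D gives
[M] = (−1+√(1+8Kc))/(4K), the dimer fraction 2[D]/c, and the closed
form c = f/(2(1−f)²K) for the concentration at which a target
fraction f is reached.

## Kinetics

*Position-dependent diffusion.*  D = σ²/τ_A per window, with τ_A the
integrated autocorrelation time (trapezoidal sum of the ACF to its
first negative value, so that for an OU process τ_A equals the
relaxation time and D is recovered exactly in expectation); errors by
block bootstrap.  D(ξ) is linearly interpolated between window means
and extrapolated as a constant.

*Association rate.*  Steady-state Smoluchowski flux with an absorbing
boundary at ξ_a = 11 Å and an equilibrium reservoir at ξ_b:
k_on = N_A [∫ e^{βw}/(4πξ²D) dξ]⁻¹.  With the default
(angular-integrated) convention the radial Jacobian is restored via
w = G + (2/β) ln(ξ/ξ_b); a `radial` mode accepts a bare radial PMF.
The solver is anchored by the Debye limit 4πDξ_aN_A (free diffusion)
and cross-checked against the Brownian first-passage oracle: in the
integrated convention the effective 1D walk feels the plateau-flat G,
for which the reservoir steady-state rate equals N_A·V_eff/(2τ)
exactly in the flat case (V_eff = 4πξ_b²∫e^{−βG}), with O(range/ξ_b)
corrections from the short-range attraction.

*Flipping MFPT.*  τ = (1/D_rot)∫_{θ0}^{θ1} e^{βF(θ′)}
∫_a^{θ′} e^{−βF(θ″)} dθ″ dθ′ with a reflecting boundary at a (0° or,
by mirror symmetry, 180°), evaluated by cumulative trapezoids and
validated against the flat-potential closed form θ₁²/(2D) and the
first-passage oracle.  F(θ) comes from projecting the bound region of
the landscape onto θ.

*Rotational diffusion (wobbling in a cone).*  τ_P2 is the integrated
autocorrelation time of P₂(cos θ); σ comes from a Gaussian fit to the
histogram of θ divided by sin θ (the entropy correction); the
small-wobble closed form D = σ²/τ_P2 is corrected by
1/(1 + σ_rad²/sin²θ̄) because the geometric sin θ term stiffens the
effective well that sets τ_P2 but not the fitted cone width.  The full
cone-angle series expansion is out of scope; the estimator recovers
generator inputs (including the published 3.8·10¹² deg²/s) to within
15 % at 10⁵ samples.

## CD post-processing

Stick spectra (excitation wavelength, rotatory strength) are broadened
with area-preserving Gaussians and scaled per molecule (strength
divided by 1 for monomers, 2 for dimers), then combined with
normalized population weights.  The broadening width has no published
value; the default FWHM is 12 nm, typical for polyene
exciton bands, and purely cosmetic — all tests are FWHM-parametric.

## What the synthetic data does and does not show

The generator emulates the *layout* of the emulated experiment (window
ladder, coordinate ranges, landscape topography, published
observables) but not molecular reality: there is no solvent, no
enthalpy decomposition, no secondary angle φ surface, and its
kinetics are scaled for desk-size runs.  Passing tests therefore
demonstrate that the estimators are correct and internally consistent
(they recover the ground truth they are given through the full
sampling → WHAM → integration chain), not that the underlying physical
values are re-derived from first principles.  Published quantities
that depend on unpublished inputs (absolute k_on, the 200 ns flipping
MFPT, CD intensities) are validated at the level of identities and
method oracles only.

## Numerical choices and degenerate inputs

* WHAM raises on empty bins (no imputation); single-window zero-bias
  input degenerates to direct Boltzmann inversion.
* Profiles re-apply the plateau-zero shift before bound-state
  integration, so additive constants cancel; P_b → 1 raises a
  saturation error rather than returning an unbounded K.
* Minima are refined by a three-point parabola; the barrier is the
  profile maximum between the two deepest minima minus the shallower
  one.
* The diffusion estimator refuses series shorter than 10⁴ points or
  with τ_A > length/50; the pipeline skips such windows (with a
  warning) when assembling D(ξ).
* Quadratures (association integral, MFPT double integral, spectra)
  are refinement-stable to <1 %, enforced by tests.
* Stochastic tests are seeded; tolerance bands are 3 standard errors
  or the stated closed-form accuracy.

Problem sizes used by the shipped analysis: 17 windows × 10⁵ recorded
samples for the pipeline and acceptance runs; 10⁵-sample series for
the OU/wobble oracle checks; 150–2000 replicas for first-passage
estimates.
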