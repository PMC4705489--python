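# ambdimer

Thermodynamics and kinetics of amphotericin B (AmB) self-association
in water, as a reusable, tested analysis pipeline for
umbrella-sampling data.

AmB is a polyene macrolide antifungal whose aggregation state in
aqueous solution — monomers vs dimers vs higher oligomers — governs
its selectivity between ergosterol-rich (fungal) and cholesterol-rich
(mammalian) membranes.  The package quantifies the first step of that
aggregation, dimerization, from biased simulations along the
interchromophore distance ξ and the inter-axis angle θ:

* **WHAM** — self-consistent reconstruction of the 1D free-energy
  profile G(ξ) from harmonic umbrella windows, and binless Boltzmann
  reweighting to the 2D surface G(ξ, θ) with basin populations and
  parallel/antiparallel statistics;
* **thermodynamics** — the unitless dimerization constant
  K = (V_box/V₀)·P_b/(1−P_b) with bound state ξ < R = 11 Å and
  standard volume V₀ = 10²⁷/(N_A c°) ≈ 1661 Å³, ΔG° = −k_BT ln K, the
  dimer fraction at a given total concentration from the 2M ⇌ D mass
  balance [M] = (−1+√(1+8Kc))/(4K), and the onset concentration
  c = f/(2(1−f)²K);
* **kinetics** — position-dependent diffusion D(ξ) = σ²/τ_A per
  window, the diffusion-controlled association rate from the
  steady-state Smoluchowski flux
  k_on = N_A [∫ e^{βw(ξ)}/(4πξ²D(ξ)) dξ]⁻¹, and the
  parallel↔antiparallel flipping time from the mean first-passage
  double integral τ = (1/D_rot)∫e^{βF}∫e^{−βF}, with D_rot estimated
  by the wobbling-in-a-cone model (P₂ autocorrelation time plus the
  width of the sin θ-corrected angular distribution);
* **CD post-processing** — Gaussian broadening of stick spectra,
  per-molecule scaling, and population-weighted composite dimer
  spectra;
* **synthetic data** — a calibrated parametric landscape with four
  bound-state basins (two parallel, two antiparallel) and a
  Metropolis-corrected Brownian-dynamics umbrella sampler that
  replaces the original molecular-dynamics engine, plus exact
  stochastic oracles (Ornstein–Uhlenbeck, wobbling, first-passage
  replicas) used to validate every estimator.

See `docs/methods.md` for the model, its assumptions and all numerical
choices.

## Worked example

```python
from ambdimer.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(), outdir="run")
print(f"dG_standard = {report.delta_g_kcal_mol:.2f} kcal/mol")
print(f"onset (10% dimeric) = {report.onset_concentration_molar*1e6:.2f} uM")
print(f"dimer fraction at 1 uM = {100*report.dimer_fractions['1e-06']:.0f}%")
print("basin populations:",
      {k: round(v, 2) for k, v in report.basin_populations.items()})
```

prints (default configuration, base seed 19109):

```
dG_standard = -7.20 kcal/mol
onset (10% dimeric) = 0.35 uM
dimer fraction at 1 uM = 22%
basin populations: {'I': 0.19, 'II': 0.33, 'III': 0.22, 'IV': 0.26}
```

The run calibrates the reference landscape to the published
observables, generates the 17-window umbrella ladder over
4 Å < ξ < 25 Å, reconstructs the profile by WHAM and integrates the
bound state: ΔG° ≈ −7.1 kcal/mol means dimers form at sub-micromolar
concentrations (10 % of molecules dimeric already at ≈0.4 μM, ≈20 % at
1 μM — therapeutic concentrations), and the four basin populations
show that parallel and antiparallel dimers are nearly equiprobable
with the antiparallel head-to-tail geometry II the most populated.
All intermediate artifacts (per-window trajectories, profile, 2D
surface, WHAM offsets, JSON report with error bars) are written to
`run/`.

The same stages are available as subcommands of the `ambdimer` console
script (`generate`, `wham`, `thermo`, `kinetics`, `spectra`,
`reproduce`), each reading and writing plain-text artifacts.

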