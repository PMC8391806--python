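# foldbind

NMR + ITC dissection of how an intrinsically disordered protein (IDP)
folds upon binding its partners — built around the docking-site motif of
the MKK4 regulatory domain, which engages two homologous MAP kinases
(JNK1 and p38α) in two different bound conformations.

The package implements, as a tested pipeline over delimited-text tables:

* **Two-site chemical exchange.** Forward simulation of ¹⁵N CEST profiles
  by Bloch–McConnell propagation (matrix exponential of the 6-dimensional
  two-state magnetization over the saturation period) and of CPMG
  relaxation dispersion by the Carver–Richards closed form; global
  least-squares fitting of the exchange rate constant *k*<sub>EX</sub> =
  *k*<sub>AB</sub> + *k*<sub>BA</sub> and bound population
  *p*<sub>bound</sub> shared across residues, and per-residue extraction
  of free/bound chemical-shift differences Δω at fixed exchange
  parameters.
* **Spin relaxation.** Mono-exponential fitting of *R*₁/*R*₁ρ decays with
  Monte-Carlo errors, the tilt-angle offset correction
  *R*₂ = (*R*₁ρ − *R*₁ cos²θ)/sin²θ with θ = arctan(ω₁/Δω), the
  rigid-rotor *R*₂ from dipolar + CSA spectral densities
  J(ω) = (2/5)τ<sub>c</sub>/(1+(ωτ<sub>c</sub>)²), and Stokes–Einstein
  scaling τ<sub>c</sub> ∝ η/T with an empirical water–glycerol viscosity
  correlation.
* **Kinetics.** *k*<sub>off</sub> = (1 − *p*<sub>bound</sub>)·*k*<sub>EX</sub>
  and *k*<sub>on</sub> = *k*<sub>off</sub>/*K*<sub>D</sub>; 1:1 binding mass
  balance; HSQC titration-intensity normalization.
* **ITC.** 1:1 (n identical sites) isotherm simulation with
  displaced-volume dilution bookkeeping, (K_D, ΔH, N) fitting, and the
  dissection ΔG = RT ln K_D, −TΔS = ΔG − ΔH, with an H-bond-equivalent
  reading of enthalpy differences.
* **Helicity.** Per-residue α-helical propensity
  f = (δ_obs − δ_rc)/(δ_helix − δ_rc), clipped to [0, 1] and averaged over
  a 3-residue window, for the free state and for bound states
  reconstructed as δ_free + Δω.
* **Synthetic data.** A generator producing every input table with the
  statistical structure of the study — slow exchange at
  *k*<sub>EX</sub> ≈ 99 s⁻¹ / *p*<sub>bound</sub> ≈ 8.7% (JNK1-like) and
  219 s⁻¹ / 6.2% (p38α-like), CEST at B₁ = 21 Hz and T_sat = 300 ms,
  ITC with 26 × 1.5 μL injections of 570 μM titrant into a 42 μM cell —
  so the whole pipeline is testable without spectrometer data.

## Worked example

Run the full two-complex pipeline on synthetic data (simulation → titration
normalization → relaxation → global exchange fit → Δω extraction → kinetics
→ ITC → helicity → comparison report):

```sh
foldbind --seed 3 --out-dir demo run
```

prints (and writes to `demo/report.txt`):

```text
two-complex folding-upon-binding comparison
package version : 0.1.0
seed            : 3
config hash     : 35d9f301e516d56e

[jnk1]
  kEX      = 98.5 +- 2.4 s-1
  p_bound  = 8.77 +- 0.10 %
  k_off    = 90 s-1
  k_on     = 6.92e+07 M-1s-1
  K_D      = 1.30 uM (N = 1.00)
  dG       = -7.90 kcal/mol
  dH       = -9.55 kcal/mol
  -TdS     = 1.66 kcal/mol (unfavorable)
  bound-state helicity > 0.5 at residues: [40, 41, 42, 43, 44, 45]

[p38a]
  kEX      = 215.2 +- 3.1 s-1
  p_bound  = 6.27 +- 0.06 %
  k_off    = 202 s-1
  k_on     = 5.03e+07 M-1s-1
  K_D      = 4.01 uM (N = 1.00)
  dG       = -7.24 kcal/mol
  dH       = -5.01 kcal/mol
  -TdS     = -2.23 kcal/mol (favorable)
  bound-state helicity > 0.5 at residues: none

ddH             = 4.5 kcal/mol
H-bond equiv.   = 3-3 bonds
affinity ratio  = 3.1
```

Reading the report: both complexes bind with similar on-rates (~5–7 × 10⁷
M⁻¹s⁻¹), so the three-fold affinity difference is an off-rate effect
(90 vs 202 s⁻¹).  The tighter complex pays an entropic penalty
(−TΔS > 0) because its docking motif folds into a helix on binding
(residues 40–45), compensated by ~4.5 kcal/mol of extra binding enthalpy
— the equivalent of two to three additional hydrogen bonds.  The weaker
complex binds extended: no helix, favorable entropy, smaller enthalpy.
This is enthalpy–entropy compensation resolved residue by residue.

Individual stages are exposed as subcommands, e.g.

```sh
foldbind kinetics dissect --kex 99 --pbound 0.087 --kd 1.3e-6
# k_off = 90.4 s-1 (printed: 90)
# k_on  = 6.95e+07 M-1s-1
foldbind relax scale-tauc --tau-ref 21.8 -t 278.15 --glycerol 0.05
# tau_c = 47.0 ns  (eta = 1.796 mPa s)
```

and the library surface mirrors them (`foldbind.fit_global`,
`foldbind.fit_isotherm`, `foldbind.helical_propensity`, …).

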