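# Methods

## Two-site exchange model

A residue exchanging between a free state A and a bound state B is
described by the total exchange rate constant k_EX = k_AB + k_BA and the
bound population p_bound, with detailed balance k_AB = p_bound·k_EX and
k_BA = (1 − p_bound)·k_EX.  Per residue the model carries the two state
shifts δ_A, δ_B (ppm on the ¹⁵N axis, relative to the carrier), the
longitudinal rates R1_A, R1_B and transverse rates R2_A, R2_B.  For a
pseudo-first-order binding equilibrium the bound-state escape rate is
k_off = k_BA = (1 − p_bound)·k_EX, and k_on = k_off/K_D with the
ITC-derived dissociation constant.  Printed rates are rounded only in
reports; derived quantities (k_on) always use unrounded inputs.

### CEST forward model

Saturation transfer is propagated in the 6-vector basis
(MxA, MyA, MzA, MxB, MyB, MzB).  For each saturation offset the evolution
matrix contains the rotating-frame offsets of both states, the B1 field
(applied along +x), relaxation and the exchange coupling; I/I0 is
MzA(T_sat)/MzA(0) with initial longitudinal magnetization at the
equilibrium populations.  The homogeneous (6-dimensional) form is used:
magnetization relaxes toward zero during saturation, with no
thermal-recovery term.  This matches the normalized-intensity convention
in which the reference I0 is acquired without the saturation period; at
offsets far from both resonances the model correctly reduces to
I/I0 = exp(−R1_A·T_sat).  A 7-dimensional inhomogeneous variant (recovery
toward thermal equilibrium) was considered and omitted: with
T_sat = 0.3 s and R1 ≈ 1.4 s⁻¹ the difference is a uniform vertical
offset absorbed by the per-residue R1 parameter, and the homogeneous form
keeps the propagator a single matrix exponential.  ppm→rad/s conversion
uses the ¹⁵N Larmor fraction |γN/γH| = 0.101396 of the ¹H frequency; the
sign convention is Δω = δ_B − δ_A > 0 for a downfield bound state.

The matrix exponential is evaluated with scipy's stacked `expm` over all
offsets (and, inside fits, over all residues) at once.  An independent
RK4 integrator at dt = 10 μs serves as the oracle; the two agree to
|ΔI/I0| < 10⁻⁶.

### CPMG forward model

R2,eff(ν_CPMG) uses the Carver–Richards closed form with
ν_CPMG = 1/(2δ), δ the spacing between refocusing pulses.  For large
echo-train arguments the arccosh is evaluated in log space to avoid
overflow.  The independent oracle propagates the complex transverse
magnetization (M+_A, M+_B) through the explicit echo train
(τ–180°–τ blocks) and measures the decay rate between T and 2T — the
steady-state echo decay rate that the Carver–Richards expression
represents — rather than a single constant-time point, whose
initial-projection transient is a definition difference, not a model
error.  Agreement is < 2% (in practice ~10⁻⁶ relative) over 50–1000 Hz
at slow-to-intermediate exchange parameters.

### Global fitting

`fit_global` shares (k_EX, p_bound) across residues; per residue Δω, R1_A
(with R1_B tied to R1_A) and R2_A, R2_B are local.  Free-state shifts
δ_A are taken as known inputs when a shift table is supplied — they come
from the assigned free-protein spectrum at far higher precision than any
fit — and are otherwise fitted, initialized from the CEST dip positions.
R2_B has a lower bound of 20 s⁻¹: the bound state is a ~90 kDa complex,
and the bound-state transverse rate is otherwise poorly identifiable at
p_bound < 10%.  The optimizer is scipy's trust-region reflective least
squares with a block-sparse Jacobian (`jac_sparsity` + `lsmr`), parameter
scales set per type (50 s⁻¹ for k_EX, 0.02 for p_bound, 0.2 ppm for
shifts, 2 and 20 s⁻¹ for free/bound R2), ftol = xtol = 10⁻⁹ and a
300-evaluation budget, which brings noiseless synthetic data back to the
truth to ~10⁻⁴ relative.  Δω sign/magnitude degeneracy (a real ambiguity
only for CPMG-only residues, which lack dip positions) is handled by a
multi-start over Δω ∈ {±0.5, ±1.5, ±3, ±5} ppm with χ² tie-breaking.
Parameter errors come from the Jacobian covariance at the optimum,
scaled by the reduced χ²; boundary-pinned global parameters are flagged.
A fit in which no residue shows a Δω distinguishable from zero is
rejected as unidentifiable.

`extract_dw` then fixes (k_EX, p_bound) and refits each residue
separately.  The Δω sign is resolved from the minor-dip position when
one is detectable; residues without a visible minor dip are returned
flagged, their |Δω| to be read as an upper bound (a coarse Δω grid scan
picks the two best starting points before refinement).

## Spin relaxation

Decays are fitted as I(t) = I0·exp(−R·t) by least squares, with the
log-linear fit as the starting point.  Duplicate delays — the schedules
include a repeat point — enter as independent observations.  Rate errors
are the standard deviation over n_mc Monte-Carlo refits with intensities
resampled from their errors (default n_mc = 1000; the pipeline uses 100,
which stabilizes errors to the two significant figures reported).  The
R1ρ→R2 tilt-angle correction folds θ into (0, π/2] so the formula is
sign-safe on either side of the carrier; θ = π/2 (on resonance) returns
R1ρ unchanged and θ = 0 is rejected as unbounded.

The rigid-rotor R2 uses reduced spectral densities
J(ω) = (2/5)·τ_c/(1+(ωτ_c)²) with the dipolar (¹H–¹⁵N) and ¹⁵N CSA terms

    R2 = (d²/8)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
       + (c²/6)[4J(0) + 3J(ωN)]

d = (μ0/4π)·ħγHγN/r³, c = ωN·Δσ/√3.  Defaults r_NH = 1.02 Å and
Δσ = −170 ppm are the conventional amide values; both are configurable,
and the 69 s⁻¹ estimate for the bound complex is reproduced within 10%
for constants anywhere in the conventional ranges (1.01–1.04 Å,
−160 to −175 ppm).  An order parameter S² = 1 is assumed (rigid rotor);
any internal motion would lower the prediction, which is why the number
is a lower bound for the true bound-state rate.

Viscosity of water–glycerol mixtures uses a Cheng-type exponential-mixing
correlation (component viscosities exp-polynomial in °C, mass-fraction
weighting exponent; % v/v converted via glycerol density 1.261 g/mL).
It gives 0.893 mPa·s for water at 25 °C and 1.796 mPa·s at 5 °C with 5%
v/v glycerol, so 21.8 ns scales to 47.0 ns via τ_c ∝ η/T — within 0.2%
of the 47.1 ns the analysis targets.  Pure water is assumed as the
reference condition of the 25 °C measurement.

## ITC

The binding model is n identical independent sites; the per-site
occupancy comes from the stable form of the binding quadratic (product
form, no catastrophic cancellation at small K_D).  Injections use
displaced-volume bookkeeping: each injection mixes instantaneously into
V0 + dV, an equal volume of mixed solution overflows, and the measured
heat is ΔH times the net complex formed in the cell after overflow.
Under this convention the summed raw heats equal ΔH times (final complex
in the cell + complex expelled over the run) exactly, which is the
mass-balance oracle the tests use.  Fits run on the per-mole-of-injectant
scale (raw heats are ~10⁻⁹ kcal, far below optimizer tolerances) with
K_D log-parameterized; errors come from the Jacobian covariance, K_D by
the delta method.  The Wiseman c-value N·[cell]/K_D is checked: c < 1
flags a low-information isotherm, c > 1000 flags K_D as an upper bound
(stoichiometric regime).  Heats of dilution can be fitted as a constant
per-injection offset (off by default).  Dissection uses
ΔG = RT ln K_D (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, 1 M standard state) and
−TΔS = ΔG − ΔH at the experiment temperature (default 293.15 K).
`hbond_equivalent` divides a ΔΔH by a per-bond enthalpy window of
1.5–2.25 kcal/mol and rounds inward, mapping 4.5 kcal/mol to 2–3 bonds.

## Helicity

Raw propensity f = (δ_obs − δ_rc)/(δ_helix − δ_rc) is clipped to [0, 1]
and smoothed with a centered 3-residue window that shrinks to the
available neighbors at the termini (no padding, no invented terminal
values).  Random-coil shifts are consumed as an input table (they come
from a neighbor-corrected predictor run at the experimental temperature
and pH; the predictor is not reimplemented).  Full-helix references
default to δ_rc plus a packaged per-residue-type ¹⁵N secondary-shift
table (−2.5 to −5.5 ppm, helix shifts upfield); because the literature
reference values are not tabulated here, helicity magnitudes are
meaningful relative to these references and profile shapes (presence and
extent of a helical segment) are the robust readout.  Prolines (no amide)
and residues whose references are closer than 0.2 ppm are excluded.
Bound-state shifts are δ_free + Δω with the exchange-model sign
convention.

## Synthetic data

The generator emulates the study conditions: a 75-residue disordered
domain (residues 12–86) whose docking motif 40–48 (KRKALKLNF) is real
sequence, with synthetic disordered filler elsewhere (positions the
analysis names — Q38, G39, A49, N50, F53, K54 — are kept).  Two presets:

* **jnk1** — slow exchange, k_EX = 99 s⁻¹, p_bound = 8.7%, K_D = 1.3 μM,
  ΔH = −9.5 kcal/mol.  The motif folds into a helix on binding: Δω for
  residues 40–45 equals 90% of the helix secondary shift of each residue
  type; flanking residues carry downfield environment shifts of 1–2 ppm.
* **p38a** — intermediate exchange, k_EX = 219 s⁻¹, p_bound = 6.2%,
  K_D = 4.1 μM, ΔH = −5.0 kcal/mol.  Binding stays extended: Δω values
  are smaller (≤ 1.8 ppm) with no helix signature, largest at residues
  41, 45, 49, 53, 54 (the CPMG anchor set).

The chosen enthalpies place ΔΔH at 4.5 kcal/mol with ΔG from the K_D
values, making the tighter complex entropically penalized and the weaker
one entropically favored — the compensation pattern the pipeline is
meant to resolve.

Acquisition defaults: CEST at both 700 and 850 MHz (B1 = 21 Hz,
T_sat = 300 ms), offsets −14 … +8 ppm around a 119-ppm carrier in
0.25 ppm steps (the amide region extends ~10 ppm upfield because of
glycines); CPMG at 600 MHz over 50–1000 Hz; R1/R1ρ decay schedules of 10
delays plus a repeat; the HSQC titration series 120:0, 120:24, 120:48,
68:46, 50:45 μM with scan-count changes; ITC as 26 × 1.5 μL of 570 μM
titrant into a 42 μM, 200 μL cell at 20 °C.  A two-field CEST set is the
standard joint-analysis practice for exchange fitting and gives fitted
uncertainties (±2.5 s⁻¹ on k_EX, ±0.1% absolute on p_bound) of the same
order as the study reports.

Noise is Gaussian and homoscedastic per table, default 1% of the
reference intensity; CPMG R2,eff noise propagates intensity noise
through σ_R2 ≈ (σ_I/T_relax)·exp(R2,eff·T_relax); ITC noise is 1% of the
largest injection heat; chemical-shift tables carry no noise (shifts are
measured orders of magnitude more precisely than intensities).  A single
scenario seed drives per-table substreams, so a fixed seed reproduces
every table bitwise, and every generator at zero noise equals its
forward model exactly.

What the generator does **not** emulate: peak overlap and missing
assignments beyond prolines, B1 inhomogeneity and off-resonance pulse
imperfections, baseline/phase artifacts, heteroscedastic intensity
errors, active-concentration errors in ITC, and any coupling between
titration broadening and exchange broadening.  Passing tests therefore
demonstrate the correctness and calibration of the analysis on idealized
data with the study's statistical structure — not robustness to the
pathologies of real spectra.

Per-residue titration broadening uses a contact weight of 1 inside the
motif, exp(−distance/8) outside with a floor of 0.1 — a monotone stand-in
for the broad interaction footprint seen in intensity profiles; only its
qualitative shape matters and only the qualitative shape is asserted.

## Pipeline and problem sizes

The orchestrated run simulates (or loads), normalizes the titration,
fits relaxation decays (Monte-Carlo n = 100), fits the global exchange
model on the preset residue subsets, extracts Δω over the motif window
(residues 33–57 by default — the region carrying exchange information;
the window is configurable), dissects kinetics and thermodynamics, and
profiles helicity.  These sizes keep a full two-complex run at about
half a minute while leaving every stage's statistics representative.
Reports embed the package version, seed and config hash; wall times go
to the run log, not the report, so identical configurations produce
byte-identical reports.

## Known limitations

* Carver–Richards is used for CPMG fitting (in-phase, two-site level);
  anti-phase coherences, TROSY effects and three-site topologies are out
  of scope.
* CEST and CPMG points are weighted only by their per-point errors; no
  relative dataset weighting is applied in joint fits.
* The rigid-rotor prediction ignores internal motion (S² = 1) and
  anisotropic diffusion.
* ITC analysis assumes integrated injection heats as input; raw power
  traces and baseline integration are not handled.
* Helicity uses the ¹⁵N dimension alone; multi-nucleus secondary-structure
  scores would be more precise on real data.
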