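# Methods

This note documents the models implemented in `pepcharge`, the assumptions
behind them, the numerical choices, and what the synthetic-data generators
do and do not emulate.

## Scientific setting

Cationic octapeptides (lysine and arginine octamers, Lys8/Arg8) bind to
supported lipid bilayers (9:1 DMPC/DMPG) used as cell-membrane mimics.
"Counting the charges" each bound peptide carries requires two independent
quantities: the **surface coverage** (how many peptides are attached) and
the **interfacial charge density** they add.  The package implements the
quantitative analysis chain for both, plus the interfacial-electrostatics
post-processing used to validate the mean-field (Gouy–Chapman) mapping
against atomistic simulation output.

## Acoustic mass (QCM-D)

A quartz crystal microbalance with dissipation monitoring reports, per odd
harmonic ν, the frequency shift Δf_ν (Hz) and dissipation shift ΔD_ν.  For
rigid films (operationally ΔD_ν/(−Δf_ν/ν) < 0.4×10⁻⁶ Hz⁻¹, strict `<` with
borderline cases flagged) the Sauerbrey relation applies:

    ΔΓ = −C · Δf_ν / ν,    C = 18 ng cm⁻² Hz⁻¹ at f₁ = 4.95 MHz.

Dissipative films are inverted with a Kelvin–Voigt layer (density ρ,
thickness h, shear viscosity η, shear modulus μ; complex shear modulus
G = μ + iωη) under semi-infinite Newtonian liquid (ρ_l = 1000 kg m⁻³,
η_l = 10⁻³ kg m⁻¹ s⁻¹).  We use the small-load approximation with the exact
one-layer load impedance

    Z_load = Z_f (Z_l + Z_f tanh γh) / (Z_f + Z_l tanh γh),
    Z_f = √(ρG),  Z_l = √(iωρ_l η_l),  γ = iω√(ρ/G),
    Δf* = i f₁ Z_load / (π Z_q),  Δf = Re Δf*,  ΔD = 2 Im Δf* / f,

with Z_q = 2 f₁ ρ_q h_q the quartz impedance derived from the sensor's mass
sensitivity constant.  This form is exact in h (no thin-film linearization)
and reduces to the Sauerbrey relation in the stiff-film limit and to the
Kanazawa liquid loading for h → 0; both limits are asserted in the tests.

**Fit.**  The film density is not identifiable jointly with h from Δf/ΔD
alone, so ρ is fixed (default 1050 kg m⁻³, config-overridable) and
(h, η, μ) are fitted in log space by weighted least squares over the joint
Δf/ΔD residuals of the supplied harmonics (default 7, 9, 11), from several
deterministic starts.  Residual weights default to per-channel noise scales
(0.5 Hz, 0.05×10⁻⁶), ideally estimated from the baseline window.
Covariance comes from the Gauss–Newton approximation at the optimum via the
delta method; non-convergence is flagged on the estimator, never silent.

## Optical mass (LSPR / de Feijter)

The localized-surface-plasmon extinction maximum shifts by Δλ_max when
material of refractive-index increment dn/dC accumulates within the
evanescent field (decay length L, sensitivity S′).  The de Feijter mass
with single-exponential decay correction is

    ΔΓ = (Δλ_max/S′) · d / [(dn/dC)(1 − e^{−d/L})],

which for adlayer thickness d ≪ L reduces to Δλ_max·L/(S′·dn/dC) — the
default when d is unknown.  Defaults: S′ = 110 nm/RIU, L = 20 nm,
dn/dC = 0.182 cm³ g⁻¹ (the standard protein value); all config-overridable.
No factor-2 decay convention is applied; the convention in use is exactly
the formula above.

Derived accounting, with N_A Avogadro's number, M the peptide molar mass
(computed from the sequence: 1043.4 g mol⁻¹ Lys8, 1267.5 g mol⁻¹ Arg8) and
z_max = 8 ionizable sidechains:

* water content = 100·(ΔΓ_acoustic − ΔΓ_optical)/ΔΓ_acoustic (the acoustic
  mass includes dynamically coupled solvent, the optical mass does not);
  clipped to [0, 100] with a warning outside;
* coverage = ΔΓ_optical·N_A/M (molecules cm⁻²);
* full-ionization charge density = coverage·z_max·e (C m⁻², the upper bound
  assuming every sidechain charged);
* occupancy = coverage × molecular footprint (defaults 4.0 nm² Lys8 /
  4.7 nm² Arg8, back-computed from published coverage–occupancy pairs and
  config-overridable).

## SHG χ⁽³⁾ isotherms (Hill/Gouy–Chapman)

Second harmonic generation from a charged interface contains a third-order
term proportional to the interfacial potential Φ₀ ("optical voltmeter"):
E_SHG ∝ A + BΦ₀.  With the bilayer charge density σ₀ fixed (−0.1 C m⁻² on
fused silica, from prior work) and peptide adsorption adding Δσ with Hill
coverage θ(c) = (K c)ⁿ/(1+(K c)ⁿ), the normalized E-field is

    E_norm(c) = [A + B·Φ₀(σ₀ + θ(c)Δσ)] / [A + B·Φ₀(σ₀)],

with the Gouy–Chapman potential of a 1:1 electrolyte (0.1 M, 298.15 K,
ε_r = 78.2 by default)

    Φ₀(σ) = (2k_BT/e)·asinh(σ/σ*),   σ* = √(8 ε_r ε₀ k_B T n₀).

Intensity-dialect inputs are converted as E = √(I/I₀) at read time.

**Fitting.**  E_norm is invariant under joint rescaling of (A, B), so A is
fixed at 1 and (B, log₁₀K, ln n, Δσ) are fitted by weighted nonlinear least
squares (weights 1/σ_E) with five deterministic multi-starts; K and n are
log-parameterized for positivity and the covariance is mapped back to
linear scale by the delta method.

**Identifiability.**  B and Δσ are nearly scale-degenerate: deepening the
plateau via |B| or via Δσ produces almost identical curves, because Φ₀ is
only mildly nonlinear over the path σ₀ → σ₀ + Δσ.  A Fisher-information
analysis at the default conditions gives a 1-σ uncertainty on Δσ of order
100% at 1% measurement noise with B free (correlation ≈ 1.0) — which is
why isotherm-only estimates of interfacial charge carry large errors and
why the sensitivity scan below matters.  When the χ⁽³⁾ response has been
calibrated independently (e.g. against the salt-screening response of the
bare bilayer), pass `fix_b=` and (K, n, Δσ) become sharp: the expected
errors drop to ~19%/9%/1.3% (1-σ) under the same conditions.  The
parameter-recovery checks therefore run in calibrated mode; the free-B
medians are reported alongside for transparency.

**Extrapolation and sensitivity.**  Measured isotherms rarely saturate
(concentrations above ~0.01 M are impractical), so one extrapolated point
can be appended at 0.1 M whose E_norm is the mean of the last k = 3
measured values; it is flagged and never double-appended.  The sensitivity
scan refits with that value scaled by (1 ± 10%) and reports the min/max of
the fitted parameters over the central and perturbed branches.

**Free energy.**  ΔG_ads = −RT ln(55.5 M · K_ads) at T = 298.15 K.  This
mole-fraction (molarity-of-water) reference uniquely reproduces the
published (K, ΔG) pairs, e.g. K = 1.6×10⁶ M⁻¹ → −45 kJ mol⁻¹; the purely
additive expectation is per-residue × length (−5.9 × 8 = −47.2 kJ mol⁻¹).
Percent ionization = 100·Δσ/σ_full compares the SHG-derived added charge
with the full-ionization bound from the optical coverage.

## Interfacial electrostatics of simulated charge profiles

Charge densities ρ(z), binned along the membrane normal with z = 0 at the
bilayer center and resolved into components (water, lipid, ions, peptide),
are post-processed as:

* σ(z) = ∫₀ᶻ ρ dz′ by the trapezoid rule (component-selectable);
* φ(z) = −(1/ε₀)∫₀ᶻ∫₀^{z′} ρ, the 1D Poisson double integral with the
  *vacuum* permittivity — all solvent charges are explicit in ρ — shifted
  so φ averages to zero over the last 5% of the grid (bulk solvent); a
  non-neutral selection leaves a boundary field, which is reported and
  warned about;
* the Grahame equation σ(φ) = σ*·sinh(eφ/2k_BT), the exact inverse of the
  Gouy–Chapman potential (asserted to machine precision);
* a one-parameter fit of matched (φ(z), σ(z)) pairs over a z-window near
  the phosphate plane (default 18–24 Å) for the apparent interfacial
  dielectric constant; since the Grahame form is linear in √ε_r the
  least-squares minimizer is closed-form.  Defaults for simulation
  profiles: 0.15 M salt, 303.15 K (the simulation conditions), distinct
  from the 0.1 M / 298.15 K SHG defaults.

**Bound-sidechain counting.**  A cationic monomer is bound when the
minimum-image distance from its representative atom (CZ for Arg, NZ for
Lys) to any lipid phosphorus is ≤ the first-RDF-peak cutoff (5.5 Å Arg,
4.5 Å Lys; boundary inclusive — the convention must be fixed for exact
oracle comparisons, and `≤` was chosen).  Distances are computed in float64
(an orthorhombic minimum-image in a few numpy lines) specifically so exact
boundary placements compare exactly; the tests verify against a plain-loop
brute-force oracle.  RDF computation itself is out of scope; the cutoffs
are configurable constants.

## Synthetic data generators

All generators are bit-reproducible for a fixed seed, and each truth is
recoverable by the corresponding analysis stage — that is the module's
reason to exist.

* **QCM-D/LSPR** (`gen_qcmd_lspr`): exponential-saturation kinetics
  Γ(t) = Γ_max(1 − e^{−k(t−t_inj)}) mapped through the Kelvin–Voigt forward
  model (acoustic channel, film-only shifts) and the inverse de Feijter
  relation (optical channel), plus additive Gaussian noise.  Scenario
  defaults are the studied systems' plateau masses (210/13 ng cm⁻² Arg8,
  34/5 ng cm⁻² Lys8), a 300 s saturation time, and film (η, μ) =
  (1.5×10⁻³ kg m⁻¹ s⁻¹, 3×10⁵ Pa) — soft enough to give a measurable
  dissipation response at 2 nm films while remaining identifiable from
  three harmonics.
* **Isotherms** (`gen_isotherm`): the Hill/GC model at the published truth
  parameters (K = 1.6×10⁶/1.0×10⁶ M⁻¹, n = 0.54/0.52, Δσ = 0.10/0.12
  C m⁻², σ₀ = −0.1 C m⁻²) with 1% multiplicative Gaussian noise over 12
  log-spaced concentrations from 1 nM to the 0.01 M experimental ceiling.
  The response amplitude B = −3.8 V⁻¹ gives a ~25% E-field drop at
  saturation, in the tens-of-percent range such measurements show.
* **GC profiles** (`gen_gc_profile`): an analytic planar Gouy–Chapman
  double layer as a component-resolved profile — a Gaussian "lipid" sheet
  carrying σ₀ at z₀ = 20 Å, the free "ions" cloud of the GC solution for
  ε_true, and a "water" component carrying the exact polarization (bound)
  charge −(1 − 1/ε_true)(lipid + ions).  Under this effective-medium
  convention the vacuum-permittivity Poisson integral of the *total*
  profile reproduces the analytic GC potential for ε_true, while the
  cumulative *free* charge (lipid + ions) obeys the Grahame relation with
  ε_true at every z in the diffuse layer — so the dielectric fit recovers
  ε_true exactly up to discretization.  The trapezoid rule mis-counts the
  abrupt cloud onset at the sheet (an O(dz) error), so the discrete charge
  deficit is deposited at the surface node; the residual error is then a
  zero-net-charge blob confined to the sheet region and the potential
  beyond is exact to O(dz²) (measured ≈ 0.01% at dz = 0.1 Å).  Neutrality
  holds to float precision by construction.  An optional ± sheet pair
  ("oriented water" stand-in) exercises component decomposition; real
  water-orientation statistics are *not* simulated.
* **Binding geometries** (`gen_binding_geometry`): one phosphorus anchor
  per peptide on a plane; planted-bound sidechains placed at
  cutoff − margin from the anchor, the rest strictly ≥ 1 Å outside every
  cutoff.  `bound_margin = 0` places sidechains axis-aligned exactly on
  the boundary (floating-point exact) to pin the inclusive convention.

**What passing tests do and do not show.**  The generators emulate the
*models* the analysis inverts, with idealized noise (Gaussian, independent)
— so recovery tests demonstrate the correctness and conditioning of the
inversions, not robustness to real-data pathologies (baseline drift,
harmonic-dependent sensitivity, bilayer defects, correlated SHG noise,
x–y-heterogeneous interfaces).  The MD-facing stages are validated against
analytic continuum profiles, not against real trajectory output.

## Known limitations

* One viscoelastic layer only; no overtone-dependent sensitivity
  corrections, no bilayer-formation kinetics.
* The Hill model inherits Langmuir-type assumptions (single site, monolayer
  limit, reversibility); n < 1 may reflect interfacial heterogeneity rather
  than anti-cooperativity, and K/Δσ from uncalibrated isotherms carry the
  large correlated uncertainties quantified above.
* χ⁽³⁾ phase-matching/coherence-length corrections are not modelled.
* The apparent-dielectric analysis assumes a 1:1 electrolyte and a planar
  interface; the z-window near the phosphate plane is an explicit
  parameter because the interface location is not sharply defined.
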