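# Methods

This note records the scientific model behind `fragrbe`, the defaults and
their rationale, the numerical choices, and the limits of what the
synthetic fields can show.

## 1. Synthetic mixed field

The generator replaces a full Monte-Carlo particle-transport code with a
1D axial model whose purpose is to produce fields with the *structure*
the mixed-field radiobiology assumes: an attenuating, slowing primary
beam; a building-up secondary-proton component; and short-ranged,
high-LET target fragments in local equilibrium.

**Geometry.** A zero-emittance pencil beam on the axis of a water
cylinder (radius 210 mm, density 1 g/cm³, ionization potential recorded
as 77 eV for provenance parity with the planning database the spectra
dialect mimics). The scored length adapts to the beam energy,
`L(E) = a (E/E0)^p + L0` with `a = 0.0022 cm`, `p = 1.77`, `E0 = 1 MeV`
and a distal margin `L0 = 3 cm`; 200 uniform depth slices; 200 kinetic
energy bins per species, spanning `[0, E_prim]` for Z ≤ 2 and
`[0, E_prim/10]` for Z ≥ 3 (the reduced upper limit buys energy
resolution for the slow recoils; the fraction is configurable).

**Primary protons.** Range from the Bragg–Kleeman rule; Gaussian range
straggling `σ_R = 0.012·R^0.935` (Bohr-like, ~1% of range); an additional
delivery energy spread of 1% of the nominal energy (typical cyclotron
scale) added in quadrature; exponential nuclear removal with mean free
path `λ = 90 cm` (~1.1%/cm, consistent with a ~330 mb inelastic
cross-section on water oxygen). At every depth slice the surviving
fluence is distributed over energy bins around the *energy-loss
consistent* representative energy (below).

**Secondary protons.** Born at rate `ν·Φ_p/λ` with `ν = 1.5` per removal
(nuclear ejectiles plus elastic hydrogen recoils), with energy a uniform
fraction of the local primary energy on [0.1, 0.9]. They are transported
with the same range–energy rule and are themselves attenuated nuclearly
along their residual path (they are protons). This produces the
characteristic build-up: their fluence is zero at the surface and peaks
at mid-range. Tertiary production is neglected.

**Target fragments.** Each species (d, t, ³He, ⁴He, ⁶·⁷Li, ⁹Be, ¹⁰·¹¹B,
¹¹·¹²C, ¹⁴N, ¹⁵·¹⁶O) is produced in proportion to the local primary
fluence with probability per cm `σ·10⁻²⁷·n_O` (`n_O = 3.34·10²² cm⁻³`).
Recoil spectra are exponential with mean 5 MeV/u for helium isotopes,
2 MeV/u for Z ≥ 3, and 5/4 MeV/u for d/t. Because their ranges are at
most a few mm, fragments are scored as the local equilibrium
slowing-down spectrum `φ(E) = Q·P(E_birth > E)/(dE/dx)`, which is the
continuum limit of the track-length estimator and conserves energy
exactly. The default cross-sections (largest channel ⁴He at 200 mb,
everything else smaller) are order-of-magnitude stand-ins constrained by
an energy balance: summed over channels they release ≈25 MeV of charged
fragment kinetic energy per nuclear removal, the scale of real p+¹⁶O
events. Without this constraint the fragment dose share inflates far
beyond the few-percent level that the mixed-field literature reports.

**Stopping power and LET.** Differentiating the Bragg–Kleeman rule gives
`S_p(E) = E^{1−p} E0^p/(ρ a p)` (MeV·cm²/g) for protons; heavier ions at
the same energy per nucleon scale as `Z²` per particle (bare charge; the
effective-charge correction is negligible above ~1 MeV/u for Z ≤ 8 and
is deliberately omitted). Energies are clamped at 0.025 MeV/u where the
power law leaves its validity range. LET in keV/μm is `S·ρ/10`.

**Monte-Carlo mode.** A seeded generator samples per-history ranges,
nuclear interaction depths, secondary emissions and fragment production
(Poisson along the summed track length), and scores fluence with the
track-length estimator per slice. It shares every closed-form ingredient
with the analytic mode, so the analytic attenuation curve is its
statistical oracle; agreement is verified at the 3σ level with 10⁵
histories. Runs are bit-reproducible for a fixed seed.

**Numerical choices.** Depositing a track segment's fluence at the
energy `E*` where `S(E*)` equals the segment's exact mean energy loss —
with a mean-preserving linear split across the two bracketing bins —
makes `Σ F·S·Δz` reproduce the exact slowing-down energy balance; the
depth-integrated dose of a non-interacting beam recovers the initial
kinetic energy to ≤0.1% (tested at 2%). The Gaussian range distribution
is integrated with 41 Gauss–Hermite nodes in the histogram scorer, and
with a 96-point Gauss–Legendre integral (after the substitution
`u = v^p`, which removes the integrable end-of-range cusp) wherever a
*smooth* depth-dose curve is needed on a fine grid.

## 2. Radiobiology

Survival is linear-quadratic-linear: `-ln s = αD + βD²` for `D ≤ D_t`,
continuing linearly with slope `S_m = α + 2βD_t` above. `S_m` is the
unique choice making the response continuously sloped at the threshold.
The inverse (dose at given effect) uses the positive quadratic root
below the threshold effect and the linear branch above — closed form, no
root finding.

**Tissues.** Registry defaults: `ab2` (α = 0.10 Gy⁻¹, β = 0.05 Gy⁻²,
α/β = 2 Gy, D_t = 8 Gy), `ab10` (α = 0.10, β = 0.01, α/β = 10 Gy,
D_t = 14 Gy), `t98` (α = 0.12, β = 0.05, α/β = 2.4 Gy, D_t = 8 Gy; the
threshold is not independently specified for this line and follows the
low-α/β exemplar).

**Ion LQ tables.** The per-species, per-energy linear coefficient is

    α_l = α_x · (1 + k·LET² / ((α/β) · (LET0 + LET) · (1 + (LET/LET_sat)²)))

with `k = 0.4 Gy·μm/keV`, `LET0 = 5 keV/μm`, `LET_sat = 100 keV/μm`;
β_l = β_x. Three properties motivate this form over a flat multiplicative
boost: (i) the quadratic low-LET behaviour keeps a pure high-energy
proton field at RBE ≈ 1 in the entrance channel, as both LEM-class models
and pristine-beam measurements require; (ii) the `1/(α/β)` scaling
reproduces the larger fragment effect in late-responding (low-α/β)
tissues — a tissue-independent *relative* α boost would, counter to
observation, produce a larger biological-dose enhancement for α/β = 10
than for α/β = 2 once pushed through the LQL inversion; (iii) the
quadratic saturation makes the amplification peak near `LET_sat` and
decline in the overkill regime, so very slow Z ≥ 6 recoils at hundreds
of keV/μm do not dominate the field average (helium is the main heavy
contributor, as expected physically). External tables can be supplied by
file to bypass the parametrization entirely.

**Mixed field.** With spectrum weights `w_l = dN/dE·ΔE` the effective
parameters are the dose-weighted means `ᾱ = Σ w S α / Σ w S`, `β̄`
analogously (an optional √β averaging mode is provided; the direct β
average is the default, matching the planning-system convention the
pipeline mirrors). The mixed response uses the tissue `D_t`, keeping ion
and photon branches symmetric. Biological dose is the photon-equivalent
dose of the LQL effect; depth profiles are evaluated either at a fixed
per-depth prescribed dose (default 2 Gy — the reference dose of the
depth-RBE curves, which no published convention fixes) or at a shared
incident-fluence scale for scenario ratio curves, where the scenarios'
physical doses must be allowed to differ. RBE at zero physical dose is
reported as missing (NaN), never zero.

## 3. SOBP planning

The beam library covers 60–230 MeV/u in 5 MeV/u steps with shared energy
grids. Intermediate "virtual" spot energies (default 1.25 MeV/u steps)
are formed by range-aligned linear interpolation between the bracketing
entries, mirroring the depth-table break-point interpolation of planning
systems. Candidate spots are restricted to Bragg peaks within
[target − 1.5 cm, target + 1.0 cm]: an unrestricted nonnegative
least-squares solve exploits the straggling tails of far-proximal beams
(astronomical weights on negligible columns) and parks distal peaks
beyond the box, which distorts both the plan and the secondary-particle
content of the field.

Physical optimization is a single nonnegative least squares of the
spot-by-depth dose matrix against a flat unit target; the primary
component of each matrix column is evaluated with the exact closed-form
depth-dose (resampling the coarse library grids leaves piecewise-linear
kinks that no weight vector can flatten). Achieved flatness
(max−min)/mean is ≈0.02% for the 160 mm box and ≈0.6% for the 280 mm box.

Biological optimization inverts the LQL response per target depth for
the physical-dose profile that delivers the prescribed biological dose
given the current field's (ᾱ, β̄), then re-solves the least squares, and
repeats; since (ᾱ, β̄) depend only weakly on the weights this converges
in a few iterations. Two stabilizers matter: a small ridge term anchors
each re-solve to the incumbent weights (the matrix is underdetermined,
so otherwise the solver hops between equivalent sparse solutions), and
(ᾱ, β̄) are smoothed with a cubic polynomial across the box (their raw
depth profiles carry resampling jitter at the spot-grid period).
Convergence is judged on the delivered dose profile; on convergence the
incumbent weights are returned, making the result an exact fixed point.
With ion tables equal to the photon parameters the procedure reproduces
the physical optimization.

## 4. Comparison analytics

LET_D (dose-averaged LET) bands — 0–1, 1–2.5, 2.5–5 keV/μm — label SOBP
positions using the *primaries-only* LET_D, the convention of the
experimental collections this analysis mirrors. RBE50/RBE80 are computed
from the closed-form LQL inverses at survival 0.5 and 0.8. The survival
chi-square is the sum of squared log-survival residuals weighted by the
per-point log-uncertainty, defaulting to unit weights when none is given
(published error bars in this domain are heterogeneous or absent); the
statistic and the weighting are exposed and swappable. The α/β-space
distance `d² = ∫(y−t)² d(α/β)` is evaluated by the trapezoidal rule on
the regression grid α/β ∈ [1, 20] Gy in 0.5 Gy steps. Experimental data
enter through a documented TSV schema; the shipped comparisons use
seeded synthetic stand-ins generated under the all-particle model with
lognormal noise (the multi-study collections are not redistributed).

## 5. Problem sizes and determinism

The default end-to-end comparison (35 library energies, two SOBPs, two
tissues, three scenarios, 39-point α/β grid) runs in well under a minute
on one core; the Monte-Carlo default is 10⁵ histories — a desk-scale
reduction of the 10⁹-history fields such analyses are usually based on,
adequate because the scored quantities enter only through ratios and
smooth averages. All stochastic components (MC transport, synthetic
data) derive from explicit seeds; a fixed seed reproduces every output,
including the JSON summary, byte for byte.

## 6. What the synthetic fields do and do not show

The generator reproduces the *structure* that drives the fragment-RBE
question: nuclear attenuation, secondary-proton build-up, short-ranged
high-LET fragments in local equilibrium, and the resulting depth pattern
of the biological-dose enhancement (maximal in the plateau at ~30–60% of
range, larger for low α/β, larger and shallower-peaked for deeper SOBP
targets, vanishing at the Bragg peak). Passing tests demonstrate the
correctness of the mixed-field calculus and the qualitative physics, not
quantitative agreement with measured nuclear data: production
cross-sections and recoil spectra are parametric stand-ins; angular
distributions, lateral scattering, neutron transport and the microscopic
(cell-scale) dose structure of very short fragments are out of scope;
secondary-proton emission uses a single uniform fraction spectrum, which
underestimates the hard leading-proton component deep in the field and
the entrance RBE contribution of soft evaporation protons. Quantities
tied to real nuclear models and measured LQ tables (e.g. the absolute
enhancement maxima) should be read as model-consistent magnitudes, not
predictions.
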