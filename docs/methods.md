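# Methods

## Density model

The working equation equates the measured apparent molar volume with the
Debye-Hückel-corrected infinite-dilution volume:

    V₂⁰(T) + A_v(T)·ω·ln(1 + b√(ωm))/b = M/d₀ − 10³/(d·d₀) · (d − d₀)/m

- `m` molality (mol/kg), `d`/`d₀` solution/solvent density (g/cm³), `M`
  molar mass (g/mol), ω = ½Σnᵢzᵢ² the valence factor.
- The right-hand side is implemented exactly as written (`M/d₀`, not
  `M/d`); at m ≤ 0.03 mol/kg the difference is below 10⁻³ cm³/mol.
- Solving for `d` gives the closed-form predictor
  `d = d₀′/(1 − m(M − d₀′·V_ψ)/10³)` with `d₀′ = d₀(T) + Δd₀` and
  `V_ψ = V₂⁰(T) + DH(m, T)`.  It is the exact inverse of the measured
  side, which the tests verify to 10⁻⁹ cm³/mol; over the studied
  molality range the curve is linear to better than 1% of its rise.

**Pure-water density** is Kell's (1975) rational polynomial (0–60 °C
enforced), cross-checked against Tanaka et al. (2001) to < 3·10⁻⁶ g/cm³
over 20–40 °C.  Note the physical span d₀(20°C) − d₀(40°C) is
0.005988 g/cm³.

**Debye-Hückel volume slope.** The default table follows the standard
Pitzer convention, anchored at A_v(0 °C) = 1.504 and A_v(25 °C) = 1.875
cm³·kg^½·mol^−3/2 with a smooth quadratic between 5 °C knots and linear
interpolation; b = 1.2 (kg/mol)^½.  Compilations in the experimental
literature differ by ~10% at fixed convention; `study_context()` ships an
alternative table scaled to A_v(25 °C) = 1.65, which reproduces the
dilute-limit contributions 0.26/1.25/1.90 cm³/mol (ω = 1/3/4 at
m = 0.03 mol/kg) quoted by the densimetric study this package models —
that study's slope source is unpublished, and 1.65 is back-derived from
those three printed numbers.  Which table is used changes V₂⁰ estimates
by ≲ 0.2 cm³/mol at these molalities.

**Per-salt fit.** Unweighted nonlinear least squares on density
residuals (single instrument, constant σ = 7·10⁻⁶ g/cm³), parameters
(V_ref, α, β) global per solute plus one Δd₀ per (series, temperature)
cell.  Levenberg-Marquardt with 10⁻¹² relative tolerances; convergence
failure raises.  Start values: two-point apparent-volume estimate for
V_ref, zeros elsewhere (the problem is nearly linear).  Covariance is
Gauss-Newton `(JᵀJ)⁻¹·s²`.  Identifiability is checked up front: α needs
≥ 2 temperatures, β ≥ 3, each cell ≥ 2 molalities; violations name the
parameter.  Model order `auto` picks the quadratic only when AIC and the
extra-sum-of-squares F-test (α = 0.05) agree; with study-scale noise the
choice moves V_ref by < 0.1 cm³/mol.

`extremum_temperature` returns the vertex `T_ref − α/(2β)` with an
extrapolation flag outside 20–40 °C.  Published per-salt tables of this
kind are not always internally consistent here (e.g. a printed NaCl
extremum of 29 °C versus ≈ 42 °C implied by the same row's α and β); this
package always computes from the parameters.

## Ionic decomposition

Additivity over binary solutes yields a design matrix whose rows hold
stoichiometric counts over the fixed ion ordering (Li⁺, Na⁺, K⁺, Mg²⁺,
Cl⁻, Br⁻, I⁻, SO₄²⁻).  For the 16-salt system the rank is 7 and the null
space is exactly the ionic charge vector — a property test checks this
for arbitrary electroneutral binary-salt pools.  The proton constraint is
applied by substitution: the HCl row keeps only Cl⁻ and the fixed
V₂⁰(H⁺, T) = −5.1 − 0.008·T − 1.7·10⁻⁴·T² (T in °C) is moved to the
observation side.  This equals the Lagrange-multiplier solution and keeps
the covariance bookkeeping trivial.

Two estimation routes (a deliberate redundancy, since the original
analysis does not say which it used):

- **per-T:** weighted least squares (weights 1/SE²) on salt-level values
  at each temperature, then a weighted quadratic refit per ion.  The
  normal-equations covariance is scaled by the reduced chi-square when it
  exceeds 1 (so inconsistent inputs widen the SEs), floored at the stated
  input SEs otherwise.
- **global:** one nonlinear least squares over all raw densities with
  per-ion (V_ref, α, β) — 24 global parameters plus one Δd₀ per
  (solute, series, T) cell — and H⁺ pinned throughout.

On additive synthetic data the two routes agree within statistical
scatter (tested at 2 SE).

**Curvature contrast.** The study reports no named test for
cation-convex vs anion-concave V₂⁰(T); the default here is a two-sided
z-test on inverse-variance-weighted group means of the quadratic
coefficients β (a reconstruction, labelled as such in the report), with
an unweighted Welch t-test behind a flag.  On the published coefficients
the z-test gives p ≈ 10⁻¹¹.

## Snapshot analysis

Orientation of a water molecule relative to the ion: `d` is the
minimum-image ion-oxygen distance; `θ` is the angle at the oxygen vertex
between O→ion and O→Q.  Q defaults to the hydrogen midpoint (the
hydrogens' center of mass for equal masses); a `com` flag uses the full
molecular center of mass instead, since descriptions in the source
analysis vary between the two.  For sulfate the reference point is the
sulfur atom, handled as a per-ion reference-atom offset.  All pair
geometry uses the minimum-image convention in the cubic box; `r_max` may
not exceed half the box edge.

Maps: counts over a (d, θ) grid; corrected mode divides each bin by its
isotropic-gas measure `(d₂³−d₁³)/3 · (cos θ₁ − cos θ₂)` and normalizes
the occupied far-field bins (outer third in d) to unit mean.  An
isotropic fluid therefore gives a flat corrected map, and a raw map
proportional to d²·sinθ — both are asserted by chi-square at α = 0.01.

V(N): per frame, `V_N = (4/3)π d₍N₎³` with `d₍N₎` the Nth-smallest
ion-oxygen distance — the sphere touches the Nth water, the simplest
reading of "bordering N molecules".  Curves are capped at the smallest
per-frame count of waters within half the box edge, so no sphere ever
exceeds the minimum-image-valid radius.  The joint fit `V = a·N + c_ion`
shares one slope across fluids (bulk water volume must not depend on the
solute) and uses points with N > 35 and mean radius < box/2; it is
plain OLS, unweighted (frame-to-frame weighting unspecified in the
source protocol).

**Caveat on SEs.** Within one fluid the V(N) points are cumulative sums
over shared frames, so OLS standard errors from the point scatter
understate the true sampling error of slope and intercepts by roughly an
order of magnitude.  Honest uncertainties in the drivers and acceptance
tests come from independent batch replicates (and a Hotelling T² for the
joint slope/intercept comparison, since the shared-slope fit makes them
strongly anti-correlated).  Single-frame-set SE quotes of the form
"slope 30.023(1) ų" should be read with the same caution.

**Unit bridge:** a slope of 29.94 ų/molecule equals
29.94 × 0.6022141 = 18.03 cm³/mol.  (A published pairing of
"30.023 ų ↔ 0.9968 g/cm³" is not consistent with this conversion, which
gives 0.9964 g/cm³ for 18.014 g/mol water; the ≈4·10⁻⁴ discrepancy is
noted rather than reproduced.)

## Synthetic worlds

**Densimetry generator.**  Defaults are the stated experimental design:
8-point geometric molality grid 10⁻³–3·10⁻² mol/kg (serial dilutions are
geometric in practice; the true per-series point count is unstated, 8 is
the recorded guess), temperatures 20–40 °C step 5, three series per
solute, Gaussian noise σ = 7·10⁻⁶ g/cm³ (declared densimeter precision),
per-(series, T) solvent offsets ~N(0, 10⁻⁵) truncated at |2·10⁻⁵| g/cm³.
Salt-level truths are assembled from the published ionic set by
additivity.  Seventeen solutes give 2040 records (the emulated campaign
reported > 800).  Fixed seed ⇒ byte-identical output.

What a green recovery test establishes — and what it does not: the world
is exactly additive, exactly quadratic in T, and homoskedastic, so
recovery tests validate the estimator, not the chemistry.  Notably, at
this stated design the ionic β SEs come out ≈ 1.8·10⁻³ cm³/mol/K²
(monovalent), several times the published ionic derivative SEs, so a
single synthetic campaign recovers the cation/anion curvature sign
pattern but not its published p < 10⁻³; that significance is established
on the published coefficients themselves.

**Solvation generator.**  Rigid TIP3P-geometry waters (O–H 0.9572 Å,
H–O–H 104.52°) in a 25 Å periodic cube, 507 waters, 10⁴ frames by
default.  Modes: `isotropic` (uniform positions, cos θ uniform),
`hard-core` (uniform outside r_ex; with `count_distribution="poisson"` an
exact hard-core Poisson fluid, for which E[V(N)] = N/ρ + (4/3)πr_ex³ —
the calibration oracle; the fixed-count default mimics trajectory data
but carries an n/(n+1) slope distortion relative to that formula),
and shell modes (`cation-like`, `anion-like`, `bulk-like`) with Gaussian
radial shells and truncated-normal θ peaks: oxygen toward the ion
(θ→180°) for cations, one hydrogen toward the ion (θ≈60°) for anions, a
donor/acceptor split for bulk water; unoriented bulk fills the box beyond
the innermost shell.  Orientation is built by aiming the O→Q axis at the
sampled θ with uniform azimuth and spin.  No water-water correlations or
hydrogen-bond network are modelled — the generator reproduces the
marginal statistics the estimators consume, nothing more.

## Registry and constants

Molar masses are stored as printed in the emulated study where available
(including Na₂SO₄ = 142.37 g/mol, which disagrees with the IUPAC value
142.04 — kept verbatim deliberately), IUPAC 2021 values otherwise.
Electroneutrality and ω = ½Σnᵢzᵢ² are enforced at construction for all
17 solutes.  Å³→cm³/mol conversion uses N_A·10⁻²⁴ = 0.6022141.

## Known limitations

- No higher-order Pitzer (solute-solute) virial terms: intentional, the
  molality range is chosen so they are negligible; bivalent-ion estimates
  (Mg²⁺) inherit the corresponding literature bias and no correction is
  attempted.
- The Δd₀ reporting ceiling (2·10⁻⁵ g/cm³) is a flag, not a constraint;
  fitted offsets can cross it by estimation noise (~2.5·10⁻⁶).
- The A_v default is a convention choice; dilute-limit DH contributions
  shift by ~12% between the standard table and the study-consistent one.
- The PDB reader handles only the minimal MODEL/ATOM/CRYST1 dialect the
  generator writes; real trajectories should be exported to the XYZ
  dialect.
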