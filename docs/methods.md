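# Methods

## Scope and model

`memrelo` simulates the relocation of a membrane receptor (VEGFR2) on the
surface of an endothelial cell while the cell adheres to and spreads on a
ligand-coated glass slide.  The physical picture has three one-way-coupled
layers:

1. **Kinematics** — the cell deforms from a suspended sphere (radius
   `r0 = 10 µm`) into a spread shape with a flat contact disc.  The
   simulator does not solve the cell mechanics; it *prescribes* the motion
   (see below), which is legitimate because the receptor transport does not
   feed back on the deformation.
2. **Ligand supply** — the substrate carries immobilized ligand.  A
   membrane point at gap `g_N` above the slide sees an available-ligand
   density (per unit *reference* membrane area)

   `S_L(X, t) = c_L^av · exp(−g_N(X, t) / ℓ_chem)`,

   maximal in the contact area (CA) and negligible beyond a few chemical
   lengths `ℓ_chem`.
3. **Reaction–diffusion on the membrane** — free receptors diffuse on the
   membrane (diffusivity `D_R`); ligands and complexes are anchored to the
   substrate and do not flow.  Binding R + L ⇌ C is far faster than both
   transport and mechanics, so species are in local chemical equilibrium at
   all times, closed by the saturation-aware mass-action relation
   `c_C = c_R · c_L / α` with

   `α(X, t) = (c_R^max c_L^max / c_C^max) · λ_a(X, t) / K_eq`,
   `K_eq = exp(−ΔG⁰ / (R T))`.

   The areal stretch `λ_a = J·|F⁻ᵀ n_R|` appears because concentrations are
   carried as referential densities (molecules per unit *undeformed*
   membrane area), which integrate to molecule counts without a Jacobian.

With `c_D = c_R − c_L` the whole base model reduces to one scalar surface
PDE, `∂c_D/∂t − Div(D_R Grad c_R) = −s_L`, plus the pointwise quadratic
constraint

`c_R² + (α − c_D) c_R − α (S_L + c_D) = 0`,

whose unique nonnegative root defines `c_R(c_D)`; ligand bookkeeping gives
`c_L = c_R − c_D` and `c_C = S_L − c_L`.

### Mobile/immobile split

Photobleaching-recovery experiments indicate that ~23% of VEGFR2 is
immobile.  The split variant partitions receptors into an immobile pool
(`c_i = c_R^i + c_C^i`, constant in time at every node: no flux, no
internalization or exposure) and a mobile pool (`c_m = c_R^m + c_C^m`)
whose free fraction alone diffuses.  Both pools share the free-ligand bath
with identical kinetic constants.  Summing the pool balances yields the
reduced closure used here: the free-ligand density solves

`c_L · (1 + (c_m + c_i)/(α + c_L)) = S_L`,

a monotone scalar condition expanded to a quadratic and solved in closed
form; the pools then split as `c_R^x = c_x α/(α + c_L)`.  This reduced form
is an algebraic consequence of the pool balances, derived here rather than
taken from elsewhere.

## Prescribed kinematics (the spreading surrogate)

The full finite-strain mechanics (viscoelastic bulk, protrusion forces,
active-set contact) is deliberately out of scope.  The default kinematics
provider replaces it with a volume-conserving **spherical-cap family**: at
every instant the cell is a spherical cap of base radius `a(t)` sitting on
a flat contact disc, with cap height solving
`π h (3a² + h²)/6 = (4/3) π r0³` (volume conservation).  The contact radius
follows the observed schedule — piecewise linear from 0 to 3.35 µm during
attachment (0–300 s), to 19.8 µm during translocation (300–600 s), constant
during the diffusion stage (600–7200 s) — reproducing the reported contact
areas of 35.3 µm² and 1232 µm².

Material points are placed by **area-fraction matching**: the reference
node holding cumulative reference-area fraction `f` (counted from the
slide-facing pole) goes to the point of the current surface (disc first,
then cap) with the same cumulative current-area fraction.  The map is
monotone, so the meridian ordering is preserved, contact nodes get
`g_N = 0` exactly, and the areal stretch is spatially uniform,
`λ_a(t) = A_current(t)/A_0` (≈ 2.07 at the final shape).

Axisymmetry holds throughout, so the surface problem reduces to a 1-D
meridian in the polar angle θ ∈ [0, π] (θ = π faces the slide).

**What the surrogate does and does not reproduce.**  Uniform stretch is the
one real idealization.  In a finite-element solution of the mechanics the
stretch concentrates at the basal membrane, so far *less* reference
membrane maps into the contact disc than the `π a²/λ̄ ≈ 595 µm²` of the
uniform map.  Since the available-ligand density is referential, the
surrogate correspondingly *overestimates* the total referential ligand
capacity `∫ S_L dA_R`.  Consequences worked out in this package's own runs:

* with `c_L^av = 60 /µm²` the capacity (≈ 36,900) still exceeds the 24,000
  receptors, so the base model ends nearly fully bound (≈ 1% free) instead
  of the ≈ 30% observed when stretch is basal-concentrated;
* the "coffee-ring" of complexes at the CA boundary during translocation is
  largely a current-density effect of non-uniform stretch (saturated older
  annuli look dim because they are stretched most); with uniform stretch
  the referential and current profiles are both maximal at the older,
  already-saturated core rather than at the rim.

The kinematics provider is pluggable (any callable `t → KinematicsFrame`
with per-node gap and stretch), so a higher-fidelity motion — including a
non-uniform stretch field — can be swapped in without touching the
chemistry or the solver.  Calibrating such a field was intentionally not
done here: no independently measured stretch distribution is available, and
fitting it to the end-state residuals would make those residuals circular.

## Discretization and time stepping

* **Space** — linear finite elements on the meridian with the
  surface-of-revolution measure `2π r0² sinθ dθ`.  Element stiffness
  integrals are exact; element mass integrals use 4-point Gauss quadrature
  with the first diagonal entry recovered from the exact spherical-zone
  area so that mass-matrix row sums telescope exactly to the sphere area.
  The degree-1 zonal eigenvalue of the discrete Laplace–Beltrami operator
  matches `2 D_R/r0² = 3.96e-3 s⁻¹` to 1e-5 relative at 200 nodes.
* **Mass lumping** — the production stepper uses the lumped mass built from
  the Voronoi zone weights (the same weights used to integrate totals).
  This makes the scheme conserve the quadrature total
  `Σ w_i (c_R + c_C)_i` to round-off (observed ≤ 1e-14 relative over full
  runs), because the stiffness annihilates constants and the mass row sums
  equal the quadrature weights.  The consistent mass matrix is assembled
  and available (`mass="consistent"`); it shifts fields only at the
  discretization level but conserves a slightly different functional, so
  lumped is the default.
* **Time** — trapezoidal (Crank–Nicolson) rule per chemo sub-step:
  `M Δc_D + (Δt/2) K (c_R^n + c_R^{n−1}) + M ΔS_L = 0`, with `S_L` and `α`
  interpolated linearly across each mechanical step.  The nodal equilibrium
  constraint is enforced pointwise after every sub-step.
* **Nonlinear solve** — because `c_R` is a smooth monotone function of the
  evolved field, each sub-step is solved by Newton iteration on the
  tridiagonal system with the exact closure derivative
  (`∂c_R/∂c_D = (c_R + α)/(c_R + c_L + α)` for the base model); a plain
  alternation between the linear solve and the closure has contraction
  factor `~(Δt/2)·λ_max(M⁻¹K)`, which exceeds 1 for the coarser chemo steps
  used in production, whereas Newton converges in 2–4 iterations at all
  step sizes (tolerance 1e-10 relative, cap 50 iterations).  Sub-steps are
  seeded with the previous increment as an initial guess.
* **Staging** — mechanical steps of 0.5 / 0.1 / 0.05 s in the three stages.
  The chemo sub-incrementation factor is configurable per stage; 100 is the
  reference value, the packaged validation runs use 10 for the two
  kinematically active stages and 1 for the frozen diffusion stage (chemo
  step 0.05 s there).  Halving every step while doubling every factor moves
  the 1800 s complex total by ~3e-9 relative, so the reported numbers are
  time-discretization-converged.
* **Verification** — against a brute-force explicit-Euler integration at a
  1000× smaller step on a 30-node attachment run, the trapezoidal scheme
  agrees to 3e-9 in total complexes; a cosθ perturbation decays at the
  closed-form rate `exp(−2 D_R t/r0²)` to 2e-5 at 200 nodes.

## Parameters

| Quantity | Symbol | Default | Units |
|---|---|---|---|
| Available ligand density | `cLav` | 90.0 (60.0 in the reduced-ligand run) | molecules/µm² |
| Ligand saturation | `cLmax` | 16000 | molecules/µm² |
| Binding free energy | `dG0` | −32949.0 | J/mol |
| Temperature | `T` | 310.15 | K |
| Equilibrium constant | `K_eq` | exp(−dG0/RT) ≈ 354058.7 | – |
| Receptor diffusivity | `D_R` | 0.198 | µm²/s |
| Chemical length | `ell_chem` | 0.2 | µm |
| Cell radius / area | `r0`, `A0` | 10.0 / 1256.64 | µm / µm² |
| Receptor count | `N_total` | 24000 (→ 19.1 /µm²) | molecules |
| Immobile fraction | — | 0.23 (→ 4.393 + 14.707 /µm²) | – |
| Contact radii | `a_attach`, `a_final` | 3.35, 19.8 | µm |
| Stage ends | — | 300, 600, 7200 | s |

The temperature is not part of the published parameter set; 310.15 K
(37 °C) is adopted because it reconciles the stated free energy with the
stated equilibrium constant to <0.05%, and it is the culture temperature of
the underlying experiment.  `c_R^max = c_C^max` is assumed, so only
`c_L^max` enters `α`.  No cap is enforced on the free-receptor density
(the saturation limits enter only through `α`), and receptor
internalization/exposure is excluded (`s_R ≡ 0`), keeping the total
receptor count exactly conserved.

## Observables

* **Totals** — quadrature of the referential fields against the zone
  weights; the totals CSV carries `t, N_R_free, N_C, N_L_free,
  N_L_available, contact_area, norm_complex` with units in the header.
* **Normalized complex curve** — `N_C(t)/N_C(1800 s)`, the total complexes
  over the whole membrane (not only the basal side), normalized the way the
  fluorescence comparison is.
* **Apical free-receptor residual** — area-weighted mean free-receptor
  density over nodes with `g_N > 1 µm`, divided by the initial density
  19.1 /µm².  The *referential* density ratio is the default: it tracks
  molecules per material membrane patch, which is what a fluorescent tag on
  a fixed receptor population reports, and it is insensitive to the
  surrogate's uniform-stretch idealization.  A current-configuration
  variant (divide by `λ_a`) is available; under uniform stretch it simply
  rescales the ratio by 1/λ_a ≈ 0.48 and is therefore dominated by the
  surrogate's stretch artifact rather than by the chemistry.
* **Ring profile** — complex density versus current radius, meridian-ordered
  from the disc center outward, in both referential and current densities.

## Electrostatic traction diagnostics

Two published attraction laws are implemented for comparison: a
screened-Coulomb form `−C (Kg+1)[(Kg+1)²+1] g⁻⁵ e^{−2Kg} ρ_rl` (defined
above the minimum approach distance `h0 = 9 nm`) and an exponential form
`−Q (g/δ_p) e^{−g/δ_p}`.  With the published constants the exponential
model — the one calibrated to make cells spread — exceeds the screened
model by roughly four orders of magnitude over the 0.1–0.5 µm gap range,
and the screened model is down to a few fN/µm² at 0.5 µm.  `ρ_rl` defaults
to the literature constant 10⁵ µm⁻²; a mode substituting the local
`min(c_R, c_L)` from a field state is provided through the parameter
object, reflecting that a constant density is only defensible if it counts
all membrane receptors.  These tractions are diagnostics only.

## Problem sizes used for the packaged results

All packaged validation runs use 200 meridian nodes (the degree-1
eigenvalue and decay checks show the spatial error at this resolution is
~1e-5 relative); the scheme-verification oracle uses 30 nodes, and the
time-step robustness check 60 nodes, where the answers are already
converged at the reported tolerances.  A full three-stage, 200-node split
run completes in about a minute with the per-stage sub-incrementation
above; with a uniform factor of 10 the base run takes a few minutes.

## Known limitations

* Uniform areal stretch (see above): end-state residuals of the *base*
  model with reduced ligand and the translocation-stage ring localization
  are the two reported observations that depend on the basal concentration
  of stretch, and the surrogate does not reproduce them quantitatively.
* Exact spherical-cap shapes: the real spread shapes are droplet-like; the
  gap profile just outside the contact rim, hence the width of the
  partially supplied annulus (`g_N ≲ 3 ℓ_chem`), differs at the
  element-size level.
* The axisymmetric reduction is exact only for axisymmetric data, which
  every scenario modeled here satisfies.
* Finite-kinetics effects are not integrated: the mass-action rate with
  finite `k_f, k_b` exists as a diagnostic only, the solver always assumes
  instantaneous equilibrium.
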