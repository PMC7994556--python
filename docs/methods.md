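# Methods

## The model

`stenoflow` computes the hemodynamic environment inside stenosis
microfluidic devices used to study shear-induced platelet aggregation: a
straight rectangular microchannel (width `Y0 = 100 µm`, height
`Z0 = 130 µm`, analysis length `X0 = 200 µm` by default) partially occluded
by a hump-shaped contraction, characterized by the stenosis level `S`
(fraction of the width occluded) and the contraction angle `α` between the
hump ramp and the unobstructed wall.  An *eccentric* device carries one hump
of height `S·Y0` on one wall (a device-insertion-like narrowing); a
*concentric* device carries two mirrored humps of height `S·Y0/2`
(a plaque-like axisymmetric narrowing).  The throat width is `Y0(1−S)` in
both cases, exactly.

The flow is steady, laminar and incompressible.  These assumptions are
justified by the operating envelope itself: the duct Reynolds number
`Re = ρ Q D_h/(µ A)` stays in the 0.1–1.6 range over the whole study
(transition is at ~2300), and the Womersley number
`Wo = (D/2)·sqrt(ρω/µ) ≈ 0.13` at a 120 bpm pulse, so pulsatility is
negligible in the microcirculation-scale device.

The quantities of interest are the scalar shear rate `γ = sqrt(2 D:D)`
(second invariant of the rate-of-strain tensor), the wall shear stress
`τ = µ γ_wall`, and the shear history `γ(x)`, `γ′(x) = dγ/dx` along the
*platelet trajectory*: the streamline passing a fixed clearance (1 µm, half
a platelet diameter) above the stenosis apex.

### Operating point

The experimental control variable is the bulk wall shear rate `γ0` of the
unobstructed channel.  The pump flow rate follows from the rectangular-duct
relation `Q = 0.12·A·D_h·γ0/λ` (device convention: `A` in µm², `D_h` in m,
`Q` in µL/min; the SI-consistent equivalent is `Q[m³/s] = 2 A D_h γ0/λ`)
with the shape factor `λ = 24/[(1−0.351·Y0/Z0)(1+Y0/Z0)]²`, which reduces to
the plane-Poiseuille value 24 as `Y0/Z0 → 0`.  For the default cross-section
this gives `Q = 1.84–36.77 µL/min` over `γ0 = 150–3000 1/s`.

### Two-dimensional representation

The geometry and flow vary only in the x–y (width-wise) plane, so the solved
problem is 2D.  The 2D line flux is chosen so that the unobstructed-channel
wall shear rate equals `γ0` exactly: `q = γ0 Y0²/6`.  This preserves the
semantics of the control variable; the 3D duct `Q` is reported alongside for
traceability.  What the 2D model cannot represent: the z-confinement of the
real duct (aspect ratio 100:130), the z-variation of the shear sampling
plane, and any secondary flow — absolute 3D peak magnitudes are therefore
out of scope, while ratios, trends and in-plane contrasts (eccentric vs
concentric) are the deliverables.

## Geometry construction

The hump is a triangular ramp pair at angle `α` whose crest is a circular
arc of radius `r` centred at `x = 0` and tangent to both ramps; the apex
height equals the hump height exactly, so the throat-width identity is exact
by construction.  For humps too small to accommodate the fillet
(`H < r(1−cos α)`) the radius is shrunk to `H/(1−cos α)`.

**Crest resolvability (why the default fillet is 10 µm).**  The only
free parameter not fixed by `S` and `α` is the crest radius.  A sweep of
`r ∈ {2, 5, 10} µm` on the default `S = 80 %`, `α = 85°` device showed that
for `r ≲ 5 µm` the crest behaves as a sharp orifice edge: the computed peak
shear grows monotonically with grid refinement (161k → 249k 1/s between
192×48 and 384×96 at `r = 2 µm`) because the edge-singularity scale is below
any affordable resolution.  At `r = 10 µm` the platelet-trajectory peak
converges cleanly (43.3k / 45.7k / 48.4k / 49.1k 1/s on 192×48 … 512×128).
The default is therefore `r = 10 µm` — also the more plausible description
of lithographically produced humps, which are rounded at the several-µm
scale — and `fillet_radius` remains a user parameter.

The grid is a boundary-fitted structured mesh: vertical lines of constant
`ξ` (refined toward the apex by a Gaussian density bump, strength 8,
width set by the hump footprint) and transfinite interpolation between the
wall profiles in `η`.  Metric terms are evaluated with the same second-order
differences the solver uses.  Entrance and exit runs of `3·Y0` precede and
follow the ±`X0/2` analysis window so the inflow is fully developed
(Stokes-flow disturbances decay like `exp(−kx/Y0)` with `k ≈ 4`).

## Flow solver

The steady variable-viscosity Navier–Stokes equations are solved in a
coupled streamfunction / stress-vorticity formulation.  With `u = ψ_y`,
`v = −ψ_x`, `ω = v_x − u_y` and `χ = µω`:

    ∇²ψ = −χ/µ
    ρ (u·∇)(χ/µ) = ∇²χ

The second equation is exact: for any solenoidal 2D field,
`curl{∇·[µ(∇u + ∇uᵀ)]} = ∇²(µω)`.  Working with `χ` keeps the viscous
operator a pure Laplacian, so shear-thinning runs are as stable as Newtonian
ones; the viscosity enters only through lagged coefficients.

Both equations are discretized with conservative second-order nine-point
stencils in mapped coordinates.  Every metric cross term is carried
implicitly — the decisive choice for this geometry, where ramp slopes reach
`tan 85° ≈ 11.4` and the sheared cells defeat deferred-correction segregated
schemes (a SIMPLE-type variant was prototyped and stalled in limit cycles at
residuals ~10⁻⁶; the coupled system converges to 10⁻⁹ and below).  The
coupled linear system is solved directly (sparse LU) inside a Picard loop
that updates the convecting velocity and, for shear-dependent laws, the
viscosity field.

* **Convection** is central (second order) for constant viscosity — at
  `Re ≤ 1.6` the cell Péclet limit is never approached — and first-order
  upwind for shear-thinning runs, whose lagged `1/µ` coefficients can be
  locally rough.
* **Boundary conditions**: fully developed inlet profile (Dirichlet `ψ`,
  `χ`) carrying `q`; no-slip walls through a one-sided second-order wall
  vorticity closure (`ω_w = −(q22/J)·(8ψ₁ − ψ₂ − 7ψ_w)/(2Δη²)`, exact for
  cubic near-wall profiles, hence for plane Poiseuille); zero streamwise
  gradient at the outlet.  The experiment's zero-gauge-pressure inlet /
  flow-rate outlet pair is replaced by this equivalent, better-posed set —
  identical at steady state.
* **Convergence** is declared at a scaled L1 residual of the coupled
  discrete equations below `10⁻⁷`, plus, for non-Newtonian runs, either a
  stress-weighted viscosity-field change below 0.1 % or a peak-shear-rate
  drift below 0.1 % over 30 iterations (see below for why the second path
  exists).  Initialization is deterministic (zero fields), so repeated runs
  are bit-identical.
* **Mass conservation** is inherited from the streamfunction: the flux
  between the walls at any axial station is `ψ_top − ψ_bottom`, pinned to
  `q` by the Dirichlet wall rows; the independent trapezoid-integrated
  velocity flux agrees to quadrature error (<1 %).
* **Pressure** is recovered after convergence from a pressure Poisson
  equation with Neumann wall/inlet conditions and gauge zero at the outlet.
  It reproduces the analytic Poiseuille gradient to 10⁻⁶ relative; its
  accuracy is secondary to the shear observables.
* **Degenerate inputs**: `S ≥ 0.97` is refused (the sheared-grid model is
  not trusted there), as are grids below 8 cells per direction and
  non-positive flow rates.

### Blood rheology and the non-monotone stress band

Working fluids: water (`ρ = 998`, `µ = 0.001003`), Newtonian blood
(`ρ = 1060`, `µ = 0.00345`), and shear-thinning blood under the generalized
power-law `µ = K(γ)γ^{n(γ)−1}` with
`K = µ∞ + δµ·exp(−(1+γ/a)·e^{−b/γ})`, `n = n∞ − δn·exp(−(1+γ/c)·e^{−d/γ})`
and `µ∞ = 0.00345 Pa s`, `n∞ = 1`, `δµ = 0.25 Pa s`, `δn = 0.45`, `a = 50`,
`b = 3`, `c = 50`, `d = 4` (all rate constants in 1/s).  Carreau, Casson and
simple power-law parameter sets are included for the multi-model benchmark
and are standard literature values, not calibrations.

Two properties of this GPL parameter set require care inside a steady
solver:

1. `µ → ∞` like `γ^{−0.45}` as `γ → 0`.  The solver evaluates the law at
   `sqrt(γ² + (0.05·γ0)²)`, a smooth low-shear regularization that caps the
   viscosity spike on zero-shear lines (channel centreline, separation
   points) where the viscous stress `µγ` vanishes anyway.  The rheology
   module itself only applies the hard floor `γ ≥ 10⁻³ 1/s`.
2. **The stress curve is non-monotone**: `τ(γ) = µγ` *falls* from 1.57 Pa
   at `γ ≈ 68 1/s` to 1.03 Pa at `γ ≈ 222 1/s` before rising again.  A
   steady boundary-value problem is ill-posed wherever the local stress
   crosses that band (three shear rates share one stress — the shear-banding
   regime), and no fixed-point iteration on the raw law settles.  The
   solver therefore uses the monotone envelope of `τ(γ)` with a minimum
   log-log slope of 0.05 (an exactly flat Maxwell plateau leaves `γ(τ)`
   indeterminate and the iteration neutrally wandering).  Both devices act
   only at shear rates far below `γ0`; at the apex, the walls and along the
   platelet trajectory the law is untouched.  Runs whose flow field
   *contains* band-crossing regions (`γ0 ≲ 200 1/s`) still cannot reach
   pointwise viscosity consistency — the converged-flow criterion for them
   is the peak-shear stationarity path above, with the peak stationary to
   <0.05 % in practice.

## Post-processing

* The shear-rate field is evaluated from nodal velocity gradients
  (`u`, `v` recovered from `ψ` with fourth-order `η` stencils, exact for
  cubic profiles so plane-Poiseuille wall shear is exact).  A width-5
  wall-parallel **median prefilter** is applied to the field and the wall
  shear-rate array: the piecewise wall profile has curvature jumps at the
  ramp–crest tangencies that excite one-to-two-node stencil artifacts, and
  without the filter those spikes (not grid-convergent) win the peak search.
  Physical peaks are tens of nodes wide and pass through the median
  unchanged.
* Wall shear stress uses the one-sided second-order normal derivative of
  the tangential velocity, `τ = µ_wall γ_wall`, arclength-parameterized,
  with parabolic sub-sample peak refinement (ties broken toward smallest
  `|x|`).  Reported in Pa; 1 Pa = 10 dyn/cm².
* Streamlines are integrated with fixed-step classical RK4 (step = quarter
  of the smallest cell edge) through bilinear velocity interpolation in
  mapped coordinates.
* The platelet trajectory is found by bisecting the seed ordinate at the
  upstream edge of the analysis window until the minimum distance between
  the traced streamline and the **crest arc** equals the clearance
  ± 0.05 µm.  (Distance is referenced to the crest, not the ramp faces;
  seeds below the dividing streamline, which stagnate or recirculate, count
  as zero clearance for bracketing.)  The 3D experimental convention — 1 µm
  above the apex at mid-height — collapses in 2D to this clearance rule.
* `γ′ = dγ/dx` is the streamwise derivative in µm⁻¹s⁻¹, computed on a
  uniform 0.1 µm resampling of the history with a 1.3 µm median and a 2 µm
  second-order Savitzky–Golay derivative window: the shear-history gradient
  is a macro-scale quantity and differentiating unsmoothed trajectory
  samples amplifies residual grid-scale wiggle without bound under
  refinement.  The smoothed gradient integrates back to the sampled history
  to well under 1 % of its range.

## Verification

* **Plane Poiseuille** (the attached closed form
  `u(y) = (6q/w³)y(w−y)`, wall shear `γ0`): the discretization is nodally
  exact — velocity error ~10⁻¹¹, wall shear and pressure gradient exact to
  roundoff.  The grid-convergence machinery flags this case as "levels
  indistinguishable" and short-circuits to the analytic value.
* **Grid convergence** uses Richardson extrapolation on three grids with
  refinement ratio 2 (`p = ln[(f1−f2)/(f2−f3)]/ln 2`, GCI with safety
  factor 1.25; non-monotone sequences are flagged non-asymptotic, not
  raised).  The default study runs the `S = 50 %`, `α = 45°` device with the
  peak-speed observable from a 96×24 base: observed order 1.96.  On the
  steep default device the platelet-trajectory peak converges monotonically
  with shrinking differences but sub-quadratically (the crest-tangency
  regions carry locally first-order error); this is stated rather than
  hidden, and is why the clean second-order verification lives on the
  moderate case.
* **Randomized geometry suite**: 500+ seeded draws over `S ∈ [0, 0.95]`,
  `α ∈ [30°, 85°]`, both placements, all passing the throat-width identity
  to 10⁻⁹·Y0 and positive-cell checks.

## Problem sizes

Defaults chosen for the package's reference analyses: default-device
comparisons (fold changes with `γ0`, eccentric-vs-concentric contrasts) on
384×96 grids (~37k cells, a Newtonian solve takes seconds on one core);
trend sweeps over `S` and `α` on 256×64; the convergence study on
96×24/192×48/384×96.  All observables shown above to be at or near their
grid-converged values at these sizes; the remaining discretization drift is
visible in the convergence tables (e.g. the eccentric peak at `γ0=2000`
moves 48.4k → 49.1k 1/s from 384×96 to 512×128).

## Known limitations

* Absolute peak magnitudes are 2D-plane values; the z-averaging and
  z-confinement of the real 130 µm-deep duct are not modelled, so full-3D
  peak values are reproduced in trend and ratio, not magnitude.
* The hump profile (trapezoid + tangent arc) is an idealization: only `S`
  and `α` are experimentally specified, and the crest radius is a free
  parameter with a resolvability-driven default.
* The GPL law is used exactly as parameterized even though its stress curve
  is non-monotone in a band; the solver's monotone envelope is a modeling
  choice inside an ill-posed regime, and low-`γ0` shear-thinning runs
  should be read with that caveat.
* No particle-resolved platelets, no viscoelasticity (Phan-Thien–Tanner or
  Giesekus-type models would be the next step for whole-blood fidelity), no
  fluid–structure interaction, no turbulence (irrelevant at `Re ≤ 2`).
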