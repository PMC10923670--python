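# Methods

This note documents the governing model, the numerical methods, the default
parameter choices and their rationale, what the synthetic study emulates,
and the known limitations of the package.

## Governing model

Steady, laminar, incompressible 2D flow of blood through a rigid channel.
In dimensionless form (lengths by the healthy channel height scale, stresses
and pressure on the viscous scale μU/L):

* continuity: ∇·U = 0
* momentum: Re (U·∇)U = −∇p + ∇·(ν_s ∇U) + ∇·σ + f
* extra-stress transport (Oldroyd-B):
  Wi (U·∇)σ + σ = 2 ν_v V(U) + Wi [(∇U)σ + σ(∇U)ᵀ], with V = ½(∇U + ∇Uᵀ).

The viscous term is kept in Laplacian form (∇·(ν_s∇U) rather than
∇·(2ν_s V)); for constant ν_s and divergence-free U the two coincide
weakly, and for the shear-thinning cases the Laplacian form is the modelling
convention adopted here.  The upper-convected terms (∇U)σ + σ(∇U)ᵀ are the
standard frame-invariant transport of the elastic stress.

The total viscosity splits as μ = μ_n + μ_v (solvent + elastic), with the
retardation/relaxation ratio λ_d/λ_x = μ_n/(μ_n+μ_v) maintained as a
derived quantity.  Four constitutive cases: Newtonian (μ_n = μ∞, no σ),
generalized Newtonian (μ_n = μ(γ̇) by the generalized Cross law, no σ),
Oldroyd-B (μ_n = μ∞ with σ), generalized Oldroyd-B (μ_n = μ(γ̇) with σ).
The shear rate is γ̇ = √(2 V:V), the definition that returns |∂U/∂y| in
simple shear.

## Parameters and scales

Whole-blood generalized Cross parameters (defaults): μ0 = 0.16 Pa·s,
μ∞ = 0.0036 Pa·s, λ = 8.2 s, a = 1.23, b = 0.64; density ρ = 1050 kg/m³.
Dimensionless viscosities are normalised by μ∞ (so the Newtonian solvent
has ν_s = 1 and the zero-shear plateau sits at μ0/μ∞ ≈ 44.4).

**Operating point.** Re ∈ (0, 3000] and Wi ∈ [0, 1] are prescribed directly
as dimensionless inputs.  The third free number is the dimensionless inlet
mean velocity `u_in`.  Its default, **u_in = 0.0608**, together with the
reference pair U_ref = 1 m/s, L_ref = 6.2 mm used to scale the Cross time
constant (Λ = λ·U_ref/L_ref ≈ 1322.6), follows the channel blood-flow
parameter set of the numerical studies this solver family is conventionally
validated against (inlet velocity 0.0608 m/s, vessel height 6.2 mm,
μ = 0.0036 Pa·s, ρ = 1050 kg/m³).  With this choice the dimensionless
velocity field reads directly in m/s-equivalent units: the healthy-axis
speed is 1.5·0.0608 = 0.0912, stenotic throats accelerate it into the
0.13–0.15 range and aneurysm bulges decelerate it into the 0.06–0.09 range
— the magnitudes reported for this class of lesion study.  The choice is a
configuration default, not a fitted quantity; every solver entry point
accepts an explicit `u_in`.

**Elastic viscosity.** No numeric μ_v accompanies the split μ = μ_n + μ_v
in the source parameter set; the default is the symmetric split μ_v = μ_n
(solvent fraction β = 1/2), configurable through `OldroydParams`.

**Geometry defaults.** Channel height D = 2 (axis at y = 1), length 16.
Two lesions of unit axial extent centred at x = 7 and x = 9 (entrance and
exit runs > 3 channel heights).  Stenosis: cosine intrusion
y = ½D(1 − (ε/D)(1 + cos πM(x))) with M(x) = 2(x − x_c)/L_s mapping each
lesion interval to [−1, 1] — M is chosen so the profile is C⁰, the throat
(depth ε) sits at the lesion centre, and the shape matches the standard
cosine-stenosis of the literature.  Aneurysm: radius ratio
h_a = 1 + (ε/2R0)(11t − 47t² + 72t³ − 36t⁴), t = (x − l0)/l_a.  Default
amplitude ε = 0.5 for both models (a 50 % diameter stenosis; bulge apex
ratio ≈ 1.21).  Note: the bulge polynomial evaluated at the lesion midpoint
gives a wall excursion of ε/4, not 3ε/4; its true maxima (≈ 0.208·ε/R0 in
ratio excess) sit near t = 1/6 and t = 5/6.  `lesion_landmarks` reports the
polynomial's actual values at these abscissae.

## Discretization

Mixed six-node triangles: quadratic (P2) velocity and extra-stress
components on all six nodes, linear (P1) pressure on corner nodes — the
inf-sup-stable Taylor-Hood pairing with stress collocated on the velocity
space.  Elements are straight-sided (subparametric); curved walls are
approximated by the boundary polyline density.  All element integrals use
the 7-point degree-5 triangle rule, exact for every product of quadratic
bases and their gradients that appears in the weak forms.

Weak forms: continuity and momentum are standard Galerkin; the pressure
gradient and viscous terms are integrated by parts, while the stress
divergence ∇·σ is tested directly (not integrated by parts).  The outflow
natural condition is therefore (−pI + ν_s∇U)·n = 0 — a uniform zero
pressure datum — and the extra stress needs boundary data only on the
inflow, where the zero-normal-extra-stress outlet condition is satisfied
identically for developed flow.  A useful consequence: plane Poiseuille
flow (Newtonian or Oldroyd-B) is an *exact* discrete solution — parabolic
velocity, linear pressure, quadratic σ11 are all representable and all
quadratures are exact — so the analytic benchmarks are recovered to solver
tolerance rather than discretization accuracy.

Boundary conditions (channel mode): inlet U = 1.5·u_in(1 − η²), V = 0 with
η the centred transverse coordinate, plus the consistent steady-shear
stress triple σ11 = 2ν_v Wi (∂U/∂y)², σ12 = ν_v ∂U/∂y, σ22 = 0; no-slip
walls (wall values override shared inlet corners); natural outflow.  A
separate all-Dirichlet mode with a pressure pin serves the manufactured-
solution harness.

## Nonlinear solve

Damped Newton iteration with the exact analytic Jacobian of every Galerkin
term, including the ∂μ/∂γ̇ coupling of the Cross law.  Because the Cross
slope dμ/dγ̇ ∝ γ̇^(b−1) is unbounded as γ̇ → 0 for b < 1, the shear rate
entering the viscosity law is smoothed, γ̇_eff = √(γ̇² + δ²) with
δ = 1e-3 (dimensionless; configurable).  Along stagnation lines such as the
jet axis this caps the effective zero-shear plateau (≈ 21·μ∞ instead of
44·μ∞ exactly at γ̇ = 0) precisely where the viscous stress ν·γ̇ vanishes,
and restores quadratic Newton convergence that otherwise stalls in a limit
cycle there.  The linear
systems use deterministic sparse LU factorisation (problem sizes here are
≤ ~1e5 unknowns).  A backtracking line search halves the step (down to
ω = 0.1) whenever the residual norm would grow.

Convergence is declared when the summed absolute nodal increment
Σ|Φⁿ − Φⁿ⁻¹| falls below 1e-5 for every field Φ ∈ {u, v, p, σ11, σ12, σ22},
with a relative-residual safety criterion (1e-8) that guards the absolute
sum against mesh-size dependence.  Non-convergence and divergence are
flagged, never silently returned.

**Continuation.** Hard operating points are reached by a monotone Reynolds
ladder (start 200, factor 2.5, end at the target), each stage warm-starting
the next; Reynolds sweeps in the pipeline warm-start each Re from the
previous one.  Continuation invariance (ramped vs direct solves agreeing
within tolerance) is tested.

**Stabilization.** SUPG-type enrichment of the stress test functions plus
streamline diffusion on momentum convection is available.  The stress
transport is an advection-reaction equation (unit reaction), so its weight
is the bounded form τ = h/(h + 2·Wi·|U|) with enrichment τ·Wi·(U·∇N): it
vanishes at no-slip walls and saturates at the classic h/2 streamline scale
in the advective limit.  The momentum term uses τ_m = h/(2|U|)·min(1, Pe/3)
with the local element Peclet number Pe = Re|U|h/2ν.  The stabilization
Jacobian freezes the advection direction (Picard-type), so Newton degrades
from quadratic to linear convergence when it is active.  In auto mode
stabilization switches on only when the estimated inlet-peak element Peclet
number Re·1.5·u_in·h/2 exceeds 60 (an empirical bound between regimes
observed Newton-stable unstabilized and divergent on channel meshes): at
the default operating point (u_in = 0.0608) plain Galerkin on quadratic
elements is clean and Newton converges unstabilized up to Re = 3000, and
all analytic verification runs see no stabilization terms.  Being
consistent, the stress SUPG leaves exact-regime solutions unchanged
(straight-channel agreement < 1e-6) and agrees with the Galerkin solution
within local discretization error near lesions.

## Meshing

The channel is a mapped rectangle, so meshing is structured and fully
deterministic: axial stations with target spacing h_far away from lesions
and h_lesion inside a half-height-padded band around each lesion (lesion
apexes are forced into the station set so the exact throat is sampled); an
even number of transverse layers (≥ 6 across the narrowest throat); each
mapped quad split into two triangles with a diagonal pattern mirrored about
the channel axis, so symmetric problems have exactly symmetric meshes and
the computed fields inherit the symmetry to solver tolerance.  Meshes
round-trip losslessly through Gmsh MSH v2.2 text files and export to ASCII
VTU for visualisation.

Default spacings h_far = 0.4, h_lesion = 0.15 give ≈ 1.8k elements and
≈ 19k unknowns per run — the problem size used for the study matrix and the
acceptance script; the verification module measures discretization orders
on finer sequences.

## Postprocessing definitions

* Axis profiles: |U| = √(u² + v²) and p sampled on the mesh line y = 1
  (stations and half-stations; pressure linearly interpolated).
* Windows: `interior` excludes one channel height at each end;
  `between` is the closed interval between the two lesion centres;
  `lesion_span` runs from the first lesion's start to the last lesion's end.
  The velocity severity metric is 100·(max − min)/max with the max taken
  over `interior` (it lands at the stenosis hub) and the min over
  `between`, matching the reported convention; pressure extrema are
  reported for both `between` and `lesion_span` with the outlet datum at
  zero.  The percent metric itself is validated against three independently
  published extremum pairs (0.1478/0.1074 → 27.33 %, 0.152/0.072 → 52.63 %,
  0.133/0.056 → 57.89 %).
* WSS: tangential component of the deviatoric traction (2ν_s V + σ)·n on
  the bottom wall, positive where the fluid drags the wall downstream;
  gradients are evaluated in each wall edge's parent element.  For
  Poiseuille flow the curve equals the analytic 3ν·u_in/a.
* Recirculation: maximal negative-WSS wall intervals, cross-checked against
  negative near-wall axial velocity; both detectors are empty whenever the
  minimum wall WSS is non-negative.

## Verification

* Plane Poiseuille (Newtonian and Oldroyd-B): exact discrete solution;
  velocity recovered to < 1e-6 relative L2, WSS to < 1 %, the steady-shear
  stress triple (2μ_v Wi γ̇², μ_v γ̇, 0) to < 1 %.
* Mass conservation: testing continuity with the constant pressure mode
  makes the inlet and outlet fluxes equal up to linear-solver residual;
  every accepted run is checked to < 1e-6 relative.
* Method of manufactured solutions: a stream-function vortex with
  sympy-derived forcing on the unit square; observed L2 orders ≈ 2.7
  (velocity, quadratic elements) and ≥ 2 (pressure) over three meshes.
* Jacobian: finite-difference directional derivatives match the assembled
  Jacobian to better than 1e-6 relative on a coarse mesh, for Newtonian,
  shear-thinning and viscoelastic cases.
* Degeneracies: GN with μ0 = μ∞ ≡ Newtonian; OD with μ_v = 0 ≡ Newtonian;
  GD with μ0 = μ∞ ≡ OD — nodal agreement to 1e-10 on a shared mesh.

## What the synthetic study does and does not emulate

The geometry module *is* the data source: idealised, mirror-symmetric 2D
channels with analytic lesion shapes.  Passing tests demonstrate correct
solution of the stated PDE system on those geometries — they do not
demonstrate fidelity to any patient: real vessels are 3D, curved, compliant
and pulsatile, blood is thixotropic beyond the Cross/Oldroyd-B description,
and physiological inflow is not a steady parabola.  Within scope, the
qualitative severity orderings (stenosis ≫ aneurysm in velocity deviation
and WSS; recirculation growth with Re in the bulges) are robust across the
constitutive cases; the absolute printed numbers depend on the lesion
amplitude ε, the inter-lesion spacing and the inflow magnitude, none of
which have canonical published values (see limitations).

## Numerical and design choices (summary)

* γ̇ = √(2V:V), the definition that recovers |∂U/∂y| in simple shear;
  smoothed by δ = 1e-3 inside the viscosity law (see above).
* Inlet parabola centred: 1.5·u_in(1 − (y−1)²) on 0 ≤ y ≤ 2 (the raw form
  "1 − y²" is negative over half the inlet).
* Momentum coefficient of the viscous term is the solvent viscosity
  (β-weighted Laplacian with β = μ_n/(μ_n+μ_v) on the total-viscosity
  scale); the elastic stress divergence supplies the remainder.
* Pressure datum: outlet, zero, via the natural boundary condition.
* Stabilization gated on element Peclet, not raw Re.
* No randomness anywhere: structured meshing, deterministic assembly
  ordering, direct solves.  Seeds accepted by the pipeline and the
  acceptance script are recorded in outputs for provenance but seed
  nothing.

## Known limitations

* The lesion amplitude ε, inter-lesion spacing, domain length and inflow
  magnitude are configuration defaults chosen once (ε = 0.5, spacing 2,
  length 16, u_in = 0.0608); published lesion-study figures do not pin them
  down, and the between-lesion velocity minimum and all pressure extrema
  are sensitive to them.  In particular the axial-pressure levels produced
  under the documented outlet-datum/viscous-scale convention do not match
  the negative pressure ranges printed in comparable studies under any
  scaling we could identify; the package reports its own convention
  faithfully rather than rescaling toward external numbers.
* Steady formulation only: no pulsatility, no transient recirculation
  dynamics; "turbulent" regimes at Re ≈ 3000 are represented by the steady
  laminar solution the equations admit.
* Straight-sided elements and the Laplacian viscous form introduce O(h)
  geometric and O(1)·∇ν modelling differences at curved, strongly
  shear-thinning walls.
* Stabilized solves converge linearly (frozen-direction Jacobian); at the
  default operating point stabilization is never engaged.
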