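# Methods

`poroperf` models steady blood perfusion of a tissue block as a
multicompartment Darcy poroelastic continuum whose porous parameters are
derived from an explicit vascular tree.  This note records the model, the
numerical choices, and the limits of what the synthetic benchmark can show.

## Model overview

The tissue is a mixture of an incompressible hyperelastic skeleton and
`nc` fluid compartments, each representing vessels in one band of the
vascular hierarchy.  Unknowns of the steady problem are the skeleton
displacement `u`, the skeleton pressure `p` (the Lagrange multiplier of the
incompressibility constraint `J - 1 = Σ_i m*_i`), and the added pore volume
`m*_i` of each solved compartment.  Per solved compartment the steady mass
balance reads

    ∇·(K00_i ∇p + K0m_i ∇m*_i) + S_i^ext + Σ_k β_{k,i,0}(p_k^pore − p_i^pore) = 0,

with the Lagrangian permeability `K00 = J F⁻¹ K0 F⁻ᵀ` and
`K0m = K00 · d(p_PV + p_c)/dm*`; momentum balance is `∇·(F S) = 0` with an
isochoric neo-Hookean stress plus the pressure term `−p J C⁻¹`.  The pore
pressure decomposes as `p^pore_i = p + p_PV(m*_i) + p_c(m*_i)`:

* `p_PV(m*) = q1 (e^{q3 v} − e^{q3 φ0}) + q2 ln(v/φ0)` with `v = m* + φ0`
  is a coronary tube law (defaults q1 = 0.022 kPa, q2 = 1.009 kPa, q3 = 80);
* `p_c = c ε / (ε² + (v − φ_crit)²)` is a soft barrier discouraging
  porosity collapse below `φ_crit` (defaults ε = 1e−3, φ_crit = 1e−5).

**Choice of the barrier scale `c`.**  The barrier derivative reaches
`−0.65 c/ε²` just above `φ_crit`; for the steady problem to remain
well-posed (a monotone pressure–porosity law, hence non-negative added-mass
diffusivity), this must stay below the tube-law slope `q2/v` throughout the
physically visited porosity range, which at ε = 1e−3 requires `c ≲ 2.5 Pa`.
The default is `c = 1 Pa`.  Larger values make `p(v)` N-shaped and the
steady problem ill-posed; the monotonicity is asserted by a test.

The skeleton shear modulus defaults to `G = 5 kPa` and the blood viscosity
to `μ = 4 mPa·s`; neither is constrained by the tube law, both are
configurable.  All internal computation uses mm–Pa–s units (flows in
mm³/s, permeabilities in mm²/(Pa·s), couplings in (Pa·s)⁻¹); mmHg and kPa
are converted at the interfaces.

## Vascular trees and the discrete reference

Synthetic coronary-like trees are grown by staged constrained constructive
optimization: terminal points are sampled uniformly in the perfusion box
under a minimum distance to the existing tree scaling as `(V/n)^{1/3}`,
each new terminal connects to the nearby segment and bifurcation point that
minimize total segment volume `Σ π r² l` (including the upstream radius
inflation the insertion causes), and radii obey Murray's law
`r_p^γ = Σ r_c^γ` (γ = 3 by default) under equal terminal outflows, which
pins the root radius to the prescribed inlet radius exactly.  The classic
intersection tests and staged perfusion-pressure constraints of the full
CCO literature are omitted; trees are binary, deterministic under a seed.

The discrete reference solution is steady Poiseuille flow: each segment a
resistor `g = π r⁴/(8 μ l)`, nodal conservation, Dirichlet pressure at the
inlet (100 mmHg) and at every unblocked terminal (0 mmHg).  Blocked
segments (a vessel and its distal subtree) are removed from the flow solve
and from all homogenization sums.

The hierarchy parameter of segment j is the total length strictly distal
to j over the total tree length.  Its own length is excluded, so terminals
are exactly 0 and the inlet tends to 1 from below as the tree grows; the
compartment boundaries near 0 are the sensitive ones, which is why the
terminal-exact convention was chosen.  Compartments are contiguous
hierarchy intervals found by a greedy binary regression tree minimizing
within-compartment radius variance, with split points at midpoints between
adjacent distinct values and a median split when no split reduces the
variance.  Intervals are closed at their lower edge (top interval closed
at 1).

## REV homogenization

Porous fields are evaluated at the element centroids of the FEM mesh and
are piecewise constant per element.  A segment belongs to the spherical
REV (radius r_R) iff its midpoint is inside (default) or, optionally, with
exact sphere clipping.  Per compartment the REV yields the porosity
`Σ π r² l / V_R`, the permeability (Model I anisotropic
`Σ π r⁴ l t⊗t/(8μV_R)`, Model II its isotropic trace, Model III a single
domain-wide isotropic value), and the inter-compartment coupling
`β = Q/(V_R Δp̄)` from junction flows whose two segments are both REV
members.  The compartment mean pressure `p̄` is the vessel-volume-weighted
*mean* (division by `Σ π r² l`, not by `V_R`), which has pressure units and
reduces to the vessel pressure for a single vessel; the printed
volume-normalized form is available behind a switch.  Negative or undefined
couplings are clamped to zero with a log message.

Compartment 1 (the few largest vessels) is never solved: its pore pressure
is the prescribed field `p̄_1` and homogenizing it is statistically
meaningless (its standard deviation exceeds its mean).  The terminal sink
of the last compartment is `S^ext = −(1/V_R) Σ Q_t` over unblocked terminal
segments that are REV members under the same inclusion rule as every other
field — using a different rule for terminals can place sinks in elements
with no vessels and makes the discrete problem unsolvable.

A small isotropic permeability floor (1e−10 mm²/(Pa·s), configurable) is
added to every tensor: it keeps the Darcy operator nonsingular where a
compartment has no vessels, and regularizes the rank-deficient tensors the
anisotropic model produces in REVs containing one or two near-parallel
vessels, while staying ≥ 4 orders of magnitude below vessel-bearing values.

## Finite elements

Equal-order P1 tetrahedra for `u`, `p` and the `m*_i`, with 4-point
(degree-2) quadrature.  Because P1–P1 violates the LBB condition for the
incompressibility constraint, the pressure equation carries a fine-scale
stabilization `(α h²/2G) ∫ J ∇p̃ · C⁻¹ ∇p` with α = 0.2 (stable range
0.1–0.3).  The sign of this term is fixed by stability analysis:
eliminating `p` must *add* the penalty `Bᵀ C⁻¹ B` to the displacement
operator.  Rigid modes of the traction-free momentum equation are pinned at
six well-separated displacement components (3-2-1 scheme); the pressure
level of the Darcy subsystem is anchored through the couplings to the
prescribed compartment-1 pressure, and a missing anchor raises an error.

Two discretization choices matter and define the exact analytic Jacobian:

* the reference porosity enters the tube law as a *nodal* P1 field
  (volume-weighted average of the element REV porosities, floored at
  1e−4).  With nodal φ0, the current porosity at any quadrature point is a
  convex combination of nodal values; element-wise φ0 would give one shared
  nodal `m*` conflicting barrier positions in adjacent elements.
* the added-mass flux is discretized in Kirchhoff form: since
  `K0m ∇m* = K00 ∇(p_PV + p_c)` exactly, the flux uses `K00 ∇z_h` with
  `z_h` the P1 interpolant of the nodal tube-law pressure `z = p_PV + p_c`.
  This is the same continuum operator but is *linear* in `z`, removing the
  doubly-exponential nonlinearity from the discrete mass balance.

The terminal sink is starved smoothly as the local pore space collapses:
the sink of an element is multiplied by `σ(s) = s²/(s² + θ²)` with `s` the
smooth harmonic mean of the element's four nodal porosity ratios `v/φ0`
and θ = 0.05.  Physically a collapsed pore space cannot supply the
prescribed outflow; numerically this prevents a sink from draining its own
supply path without bound in under-resolved REV configurations.

## Nonlinear solution strategy

The solver works in pore-pressure variables: the nodal unknown of each
solved compartment is `z = p_PV + p_c`, with `m*(z)` recovered by inverting
the monotone tube law per node.  In `z` the exchange sources are affine and
the chain rule `dm/dz = 1/p'(m)` exactly equilibrates the tube-law
stiffness — Newton on `m*` (or on a log-porosity variable) overshoots the
exponential/logarithmic branches catastrophically.  `z` is confined to a
box: upward a generous multiple of the driving pressure, downward
`q2 ln(10⁻³)` (porosity one thousandth of reference), far outside any
physical equilibrium.

The driver performs staggered sweeps — an active-set Newton solve of the
mass subsystem at frozen `(u, p)` using a cached geometric operator, then
a damped Newton solve of the finite-strain elasticity pair at frozen `m*`
— followed by a monolithic Newton polish.  The coupling between the two
subsystems is weak (the skeleton pressure is of order `G` times the
volumetric strain, far below the pore-pressure scale), so a few sweeps
reach the monolithic basin.  The mass solve starts from a warm state that
inverts the tube law against the REV-mean Poiseuille pressures.  Implicit-
Euler pseudo-time damping is engaged automatically if a mass solve stalls.

**Porosity-floor variational inequality.**  In severely under-resolved
configurations (small r_R, few vessels per REV, strongly anisotropic
tensors) the prescribed sinks can exceed what the local permeability can
transport at any admissible porosity; the steady equations then have no
solution inside the box.  The solver returns the KKT point of the
box-constrained problem instead: dofs pinned at the porosity floor with an
outward residual are excluded from the convergence norm, and their summed
residual is reported as `flow_deficit` (mm³/s) in the solver info.  At the
benchmark scale the deficit is zero for most sweep points and a few tens
of mm³/s (≲ 0.01 % of inlet flow) at the sparsest ones.

Block residual norms are measured against data-based scales built without
cancellation (stress disequilibrium at the driving pressure for momentum,
a 1 % volume mismatch for incompressibility, the source magnitude for each
mass balance); the relative tolerance is 1e−8.

## Validation metrics

`Perr` is the inlet-normalized RMS difference between the continuum pore
pressure interpolated at unblocked vessel midpoints (using the same nodal
`z` field the solver discretizes) and the mean Poiseuille segment pressure.
Compartment-1 vessels are included by default (their continuum value is the
prescribed `p̄_1`), with a switch to exclude them.  MBF fields compare
`β_{nc−1,nc}(p_{nc−1}^pore − p_nc^pore)` against the REV junction-flow
density `Q_{nc−1,nc}/V_R`, with an element-wise relative error floored at
1e−12 s⁻¹.

## The synthetic benchmark, and what it does not show

The benchmark grows 2,000-terminal trees in a 100 mm cube (inlet radius
3 mm, pin = 100 mmHg, pout = 0) and sweeps r_R ∈ {3,…,10} mm,
nc ∈ {2, 3}, permeability Models I–III, several seeds, healthy and
blocked scenarios.  The default blockage occludes the branch feeding
closest to 10 % of the terminals — a sizeable single-vessel occlusion that
still leaves most of the domain perfused.  The default FEM mesh is 6³ cells (6·6³ tets); the
acceptance suite uses 5³ cells to keep the full sweep tractable, and those
sizes are stated here as the package's own study sizes.

This is a *scaled-down* study: at 2,000 terminals the mean terminal
spacing is ≈ 8 mm, so an r_R = 3–10 mm REV contains only a handful of
vessels, while a 50,000-terminal network has spacing ≈ 2.7 mm and tens of
vessels per REV.  Three consequences observed consistently across seeds:

* `Perr(r_R)` decreases monotonically over the swept range — the
  over-averaging upturn that creates an interior optimum appears only at
  radii beyond the sweep for this vessel density;
* the anisotropic Model I is slightly *worse* than the isotropic Model II:
  with one or two vessels per REV the anisotropic tensor is nearly rank-1,
  and the missing transverse permeability starves regions the real network
  feeds through connectivity the REV cannot see.  The heterogeneous models
  do beat the homogeneous Model III near the optimal radius, and the
  blockage scenario degrades Model III the most — both scale-robust
  effects;
* nc = 3 is not better than nc = 2 here: the middle compartment is too
  thinly populated at this tree size for its couplings to be well
  estimated.

Passing tests therefore demonstrate the correctness of the machinery
(closed forms, conservation, convergence order, thermodynamic consistency)
and the scale-robust qualitative effects; they do not demonstrate the
full-scale anisotropy benefit or the interior REV optimum, which require
vessel densities this desk-scale study deliberately does not reach.

## Known limitations

* Steady state only; the data model keeps `m*` so the unsteady extension
  is possible, but no time integration is provided.
* Trees are strictly binary with straight segments; no junction pressure
  losses; Newtonian rheology.
* The CCO variant omits intersection avoidance and staged perfusion
  pressures.
* The porcine-ventricle geometry of the original study is not available;
  the package accepts generic segment tables and cube meshes instead.
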