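# poroperf

Multicompartment Darcy poroelastic perfusion modelling, parameterized from
explicit vascular trees.

Blood perfusion of the myocardium (and similar dense microvascular organs)
is often modelled as flow through a porous continuum, but a single Darcy
compartment cannot distinguish arterial, arteriolar and capillary
pressures, and homogeneous porous parameters miss the strong spatial
heterogeneity of real vasculature — which matters most in disease, e.g.
when a vessel is blocked.  `poroperf` implements the full workflow for a
*patient-specific* multicompartment alternative:

1. **Vascular tree** — generate a coronary-like binary tree by constrained
   constructive optimization (CCO; Murray-law radii
   `r_p^γ = Σ r_c^γ`, volume-minimizing bifurcations), or read a segment
   table from file.
2. **Discrete reference** — solve steady Poiseuille flow on the tree
   (conductance `g = π r⁴ / 8 μ l`, nodal conservation, pressure boundary
   conditions at inlet and terminals).
3. **Compartments** — label each vessel with the hierarchy parameter
   `ζ_j = l_{D,j}/l_T` (distal length over total length; 0 at terminals)
   and partition the ζ-axis into `n_c` compartments by a regression tree
   minimizing within-compartment radius variance.
4. **Homogenization** — average the labelled, flow-solved tree over
   spherical representative elementary volumes (REVs) into per-compartment
   porosities `φ_i = Σ π r² l / V_R`, permeability tensors
   (anisotropic `Σ π r⁴ l t⊗t / 8 μ V_R`, isotropic, or homogeneous),
   inter-compartment coupling constants `β = Q/(V_R Δp̄)`, the prescribed
   first-compartment pressure field, and the terminal sink density.
5. **Continuum solve** — stabilized P1–P1 finite elements for the coupled
   steady problem: per-compartment Darcy mass balance with a nonlinear
   coronary tube law for vessel compliance, finite-strain neo-Hookean
   momentum balance, and the incompressibility constraint
   `J − 1 = Σ m*_i`.
6. **Validation** — interpolate the continuum pore pressure at vessel
   midpoints and compare with the discrete Poiseuille pressures through
   the inlet-normalized RMS error
   `Perr = sqrt( (1/N_v) Σ_j ((p^pore(X_j) − p_j^PL)/p_in)² )`,
   plus myocardial-blood-flow (MBF) density comparisons and sweep studies
   over REV radius, compartment count, permeability model, and
   vessel-blockage scenarios.

The science and the numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
import numpy as np
import poroperf as pp

box = pp.Box.cube(100.0)                        # 100 mm perfusion cube
tree = pp.generate_cco_tree(box, 200, 3.0, seed=1)
flow = pp.solve_poiseuille(tree, pp.FlowBCs.from_mmhg(100.0, 0.0))

labels = pp.hierarchy_parameters(tree)
scheme = pp.partition_compartments(labels, tree.radius, 2)
comp = pp.assign_compartments(tree, scheme, labels)

mesh = pp.build_cube_mesh(4, 100.0)
fields = pp.compute_porous_fields(tree, flow, comp, 2, mesh.centroids,
                                  pp.REVSpec(radius=12.0), model="II",
                                  mu=0.004, domain_volume=mesh.total_volume)
state, info = pp.newton_solve(mesh, fields, pp.MaterialParams(),
                              pp.SolverConfig())
```

which prints, with the quantities inspected along the way:

```
tree: 399 segments, 200 terminals
inlet flow: 474228.5 mm^3/s
max nodal imbalance: 8.38e-15
zeta_crit: [1.     0.0343 0.    ]
mean compartment-2 porosity: 4.25e-03
converged in 28 Newton iterations (3 sweeps)
Perr = 0.147 over 399 vessels
```

Reading: the 200-terminal tree carries 4.7·10⁵ mm³/s at 100 mmHg driving
pressure with machine-precision mass conservation; the regression tree
places the compartment boundary at ζ ≈ 0.034 (the handful of large feeding
vessels vs. everything distal); and the two-compartment continuum
reproduces the discrete pore pressures to ≈ 15 % of the inlet pressure at
this deliberately small tree size.

A command-line interface mirrors the pipeline stage by stage:

```bash
poroperf generate --terminals 2000 --seed 1 --out tree.csv
poroperf poiseuille tree.csv --out flow.csv
poroperf solve tree.csv --rev-mm 8 --nc 2 --model II --out solution.vtk
poroperf run --config run.yaml        # five-stage pipeline with manifest
```

All artifacts are plain text (CSV segment/flow tables, legacy-ASCII VTK
meshes and fields, JSON reports with SHA-256 stage checksums).

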