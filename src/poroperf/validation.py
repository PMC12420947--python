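"""Continuum-vs-network validation: pore-pressure error, MBF, benchmark sweeps.

The continuum solution is judged against the discrete Poiseuille reference
that parameterized it: the Darcy pore pressure is interpolated at every
vessel midpoint and compared to the mean Poiseuille segment pressure through
the inlet-normalized RMS error

    Perr = sqrt( (1/N_v) sum_j ((p^pore(X_j) - p_j^PL) / pin)^2 ).

Myocardial blood flow is compared through the volumetric flow density into
the final (microvascular) compartment: continuum
MBF_D = beta_{nc-1,nc,0} (p_{nc-1}^pore - p_nc^pore) versus network
MBF_PL = Q_{nc-1,nc}^PL / V_R per REV.

``run_benchmark`` drives the full generate -> flow -> parameterize -> solve
-> validate pipeline over sweeps of REV radius, compartment count,
permeability model, seed, and healthy/blocked scenarios.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import MaterialParams, pore_fluid_pressure
from .fem import (SolutionState, SolverConfig, newton_solve,
                  nodal_reference_porosity)
from .homogenization import (PorousFields, REVSpec, build_membership,
                             compute_porous_fields, junction_flow_field)
from .mesh import TetMesh, build_cube_mesh, interpolate_p1, locate_points
from .network_flow import FlowBCs, NetworkFlowSolution, solve_poiseuille
from .units import mmhg_to_pa
from .vasculature import (Box, VascularNetwork, apply_blockage,
                          assign_compartments, generate_cco_tree,
                          hierarchy_parameters, partition_compartments)

__all__ = ["interpolate_pore_pressure", "pressure_error", "mbf_fields",
           "BenchmarkConfig", "ValidationReport", "run_benchmark",
           "default_blockage_segment"]

log = logging.getLogger(__name__)


def interpolate_pore_pressure(state: SolutionState, fields: PorousFields,
                              mesh: TetMesh, points: np.ndarray,
                              compartment_of_point: np.ndarray,
                              params: MaterialParams) -> np.ndarray:
    """Continuum pore pressure at given points, Pa.

    For a point attributed to solved compartment i the value is
    p(X) + p_i^PV(X) + p_i^c(X) with p, m_i* and the nodal reference
    porosity P1-interpolated (the same discrete fields the solver used);
    compartment-1 points return the prescribed p1bar of the containing
    element.  Points outside the mesh raise.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    comp = np.asarray(compartment_of_point, dtype=np.int64)
    elem, bary = locate_points(mesh, points)
    if np.any(elem < 0):
        raise ValueError(f"{int(np.sum(elem < 0))} points lie outside the mesh")
    out = np.empty(len(points))
    is1 = comp == 1
    out[is1] = fields.p1bar[elem[is1]]
    p_at = interpolate_p1(mesh, state.p, elem, bary)
    phi0_node = nodal_reference_porosity(mesh, fields, params)
    # interpolate the nodal tube-law pressure z = p_PV + p_c (the P1 field
    # the solver discretizes) rather than re-evaluating the law at
    # interpolated m*
    z_node = pore_fluid_pressure(state.m_star, phi0_node, params).total
    for i in range(2, fields.nc + 1):
        seli = comp == i
        if not np.any(seli):
            continue
        z_at = interpolate_p1(mesh, z_node[:, i - 2], elem[seli], bary[seli])
        out[seli] = p_at[seli] + z_at
    return out


def pressure_error(p_pl: np.ndarray, p_pore: np.ndarray, pin: float) -> float:
    """Inlet-normalized RMS pore-pressure discrepancy Perr (dimensionless)."""
    p_pl = np.asarray(p_pl, dtype=float)
    p_pore = np.asarray(p_pore, dtype=float)
    if p_pl.size == 0:
        raise ValueError("no vessels to compare")
    if p_pl.shape != p_pore.shape:
        raise ValueError("pressure arrays must have equal length")
    return float(np.sqrt(np.mean(((p_pore - p_pl) / pin) ** 2)))


def mbf_fields(state: SolutionState, fields: PorousFields,
               network: VascularNetwork, flow: NetworkFlowSolution,
               comp: np.ndarray, mesh: TetMesh, params: MaterialParams,
               mem=None, floor: float = 1e-12):
    """(MBF_D, MBF_PL, MBF_err) per evaluation point (element centroids).

    MBF_err is the elementwise relative error |MBF_D - MBF_PL| divided by
    max(|MBF_PL|, floor).
    """
    nc = fields.nc
    if nc < 2:
        raise ValueError("MBF needs at least two compartments")

    phi0_node = nodal_reference_porosity(mesh, fields, params)
    z_node = pore_fluid_pressure(state.m_star, phi0_node, params).total

    def pore_elem(i: int) -> np.ndarray:
        if i == 1:
            return fields.p1bar
        p_e = state.p[mesh.tets].mean(axis=1)
        z_e = z_node[:, i - 2][mesh.tets].mean(axis=1)
        return p_e + z_e

    beta = fields.beta0[:, nc - 2, nc - 1]
    mbf_d = beta * (pore_elem(nc - 1) - pore_elem(nc))
    Q = junction_flow_field(network, flow, comp, fields.points, fields.rev,
                            k=nc - 1, i=nc, mem=mem)
    mbf_pl = Q / fields.rev.volume
    err = np.abs(mbf_d - mbf_pl) / np.maximum(np.abs(mbf_pl), floor)
    return mbf_d, mbf_pl, err


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

def default_blockage_segment(network: VascularNetwork,
                             target_fraction: float = 0.10) -> int:
    """Deterministic 'large vessel' for blockage scenarios.

    Picks the segment whose distal subtree feeds closest to
    ``target_fraction`` of all terminals (ties: larger radius, then lower
    index) - a sizeable branch occlusion that still leaves most of the
    domain perfused, as in a single-vessel disease scenario.
    """
    counts = np.zeros(network.n_segments)
    counts[network.is_terminal] = 1
    order = network.topological_order()
    for i in order[::-1]:
        p = network.parent[i]
        if p >= 0:
            counts[p] += counts[i]
    total = counts[network.root_id]
    cand = [i for i in range(network.n_segments) if network.parent[i] >= 0]
    if not cand:
        raise ValueError("tree has no blockable segment")
    best = min(cand, key=lambda i: (abs(counts[i] / total - target_fraction),
                                    -network.radius[i], i))
    return int(network.ids[best])


@dataclass
class BenchmarkConfig:
    """Sweep specification for the cube perfusion benchmark."""

    domain_size_mm: float = 100.0
    n_terminals: int = 2000
    inlet_radius_mm: float = 3.0
    pin_mmhg: float = 100.0
    pout_mmhg: float = 0.0
    mu: float = 0.004
    mesh_n: int = 6
    rev_radii_mm: tuple = (3.0, 4.0, 5.0, 6.0, 8.0, 10.0)
    nc_list: tuple = (2, 3)
    models: tuple = ("I", "II", "III")
    seeds: tuple = (1, 2, 3)
    scenarios: tuple = ("healthy",)
    include_compartment1: bool = True
    material: MaterialParams = field(default_factory=MaterialParams)
    solver: SolverConfig = field(default_factory=SolverConfig)


@dataclass
class ValidationReport:
    """Tidy table of benchmark results plus per-run diagnostics."""

    table: pd.DataFrame

    def perr_curve(self, nc: int, model: str = "I", scenario: str = "healthy"):
        df = self.table.query("nc == @nc and model == @model and scenario == @scenario")
        return df.groupby("rR")["Perr"].median()

    def model_medians(self, scenario: str = "healthy"):
        """Median-over-seeds Perr at each model's best REV radius."""
        df = self.table.query("scenario == @scenario")
        med = df.groupby(["model", "nc", "rR"])["Perr"].median()
        return med.groupby(["model", "nc"]).min()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot_perr_curves(self, path=None, scenario: str = "healthy"):
        """Median Perr vs REV radius, one panel per nc, one line per model."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        df = self.table[self.table.scenario == scenario]
        ncs = sorted(df.nc.unique())
        fig, axes = plt.subplots(1, len(ncs), figsize=(5 * len(ncs), 4),
                                 squeeze=False)
        for ax, nc in zip(axes[0], ncs):
            for model in sorted(df.model.unique()):
                med = (df[(df.nc == nc) & (df.model == model)]
                       .groupby("rR")["Perr"].median())
                ax.plot(med.index, med.values, marker="o",
                        label=f"Model {model}")
            ax.set_xlabel("REV radius $r_R$ (mm)")
            ax.set_ylabel("$P_{err}$")
            ax.set_title(f"$n_c$ = {nc}")
            ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _perr_for_solution(state, fields, network, flow, comp, mesh, params,
                       pin, include_compartment1=True):
    open_seg = np.flatnonzero(~network.blocked)
    if not include_compartment1:
        open_seg = open_seg[comp[open_seg] != 1]
    pts = network.midpoints[open_seg]
    from .mesh import locate_points as _loc
    elem, _ = _loc(mesh, pts)
    inside = elem >= 0
    if np.any(~inside):
        log.warning("excluding %d vessel midpoints outside the mesh",
                    int(np.sum(~inside)))
    sel = open_seg[inside]
    p_pore = interpolate_pore_pressure(state, fields, mesh,
                                       network.midpoints[sel], comp[sel], params)
    return pressure_error(flow.p_seg_mean[sel], p_pore, pin), len(sel)


def run_benchmark(config: BenchmarkConfig) -> ValidationReport:
    """Run the full pipeline over every sweep point; returns a tidy report."""
    bcs = FlowBCs.from_mmhg(config.pin_mmhg, config.pout_mmhg, config.mu)
    pin = mmhg_to_pa(config.pin_mmhg)
    box = Box.cube(config.domain_size_mm)
    mesh = build_cube_mesh(config.mesh_n, config.domain_size_mm)
    centroids = mesh.centroids
    rows = []
    for seed in config.seeds:
        t0 = time.perf_counter()
        healthy = generate_cco_tree(box, config.n_terminals,
                                    config.inlet_radius_mm, seed=seed)
        labels = hierarchy_parameters(healthy)
        log.info("seed %d: tree with %d segments in %.1fs", seed,
                 healthy.n_segments, time.perf_counter() - t0)
        for scenario in config.scenarios:
            if scenario == "healthy":
                network = healthy
            elif scenario == "blocked":
                network = apply_blockage(healthy,
                                         default_blockage_segment(healthy))
            else:
                raise ValueError(f"unknown scenario {scenario!r}")
            flow = solve_poiseuille(network, bcs)
            for nc in config.nc_list:
                scheme = partition_compartments(labels, healthy.radius, nc)
                comp = assign_compartments(network, scheme, labels)
                for rR in config.rev_radii_mm:
                    rev = REVSpec(radius=rR)
                    mem = build_membership(network, centroids, rev)
                    state_prev = None
                    for model in config.models:
                        try:
                            fields = compute_porous_fields(
                                network, flow, comp, nc, centroids, rev,
                                model=model, mu=config.mu,
                                domain_volume=mesh.total_volume, mem=mem)
                            state, info = newton_solve(mesh, fields,
                                                       config.material,
                                                       config.solver,
                                                       state0=state_prev)
                            state_prev = state
                            perr, n_v = _perr_for_solution(
                                state, fields, network, flow, comp, mesh,
                                config.material, pin,
                                config.include_compartment1)
                            rows.append(dict(seed=seed, scenario=scenario,
                                             nc=nc, rR=rR, model=model,
                                             Perr=perr, n_vessels=n_v,
                                             newton_iters=info["iterations"],
                                             inlet_flow=flow.inlet_flow,
                                             status="ok"))
                        except Exception as exc:  # noqa: BLE001
                            log.error("stage failure seed=%s scenario=%s nc=%s "
                                      "rR=%s model=%s: %s", seed, scenario, nc,
                                      rR, model, exc)
                            rows.append(dict(seed=seed, scenario=scenario,
                                             nc=nc, rR=rR, model=model,
                                             Perr=np.nan, n_vessels=0,
                                             newton_iters=-1,
                                             inlet_flow=flow.inlet_flow,
                                             status=f"error: {exc}"))
    return ValidationReport(table=pd.DataFrame(rows))
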