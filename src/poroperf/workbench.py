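"""Reproducible experiment driver and deterministic fixtures.

``make_fixture`` returns the named deterministic objects used throughout the
test-suite (tiny hand-built trees with exact Murray radii, seeded CCO trees,
structured cube meshes).  ``run_pipeline`` executes the five-stage pipeline
(generate -> flow -> parameterize -> solve -> validate) from a declarative
:class:`RunConfig`, writing every stage artifact with a checksum manifest so
that reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constitutive import MaterialParams
from .fem import SolverConfig, newton_solve
from .homogenization import REVSpec, compute_porous_fields
from .mesh import build_cube_mesh, write_vtk_mesh
from .network_flow import FlowBCs, solve_poiseuille
from .units import mmhg_to_pa
from .validation import _perr_for_solution
from .vasculature import (Box, VascularNetwork, assign_compartments,
                          generate_cco_tree, hierarchy_parameters,
                          partition_compartments, read_segment_table,
                          write_segment_table)

__all__ = ["make_fixture", "RunConfig", "run_pipeline", "split_seed"]


def split_seed(seed: int, stage: str) -> int:
    """Derive an independent, reproducible per-stage seed (< 2^31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _murray_child(r_parent: float, gamma: float = 3.0) -> float:
    return r_parent * 2.0 ** (-1.0 / gamma)


def _y3() -> VascularNetwork:
    """3-segment Y: 2 mm trunk + two 1 mm children, Murray gamma=3 radii."""
    r0 = 1.0
    r1 = _murray_child(r0)
    prox = np.array([[0, 0, 0], [0, 0, 2], [0, 0, 2]], dtype=float)
    dist = np.array([[0, 0, 2], [0.6, 0, 2.8], [-0.6, 0, 2.8]], dtype=float)
    return VascularNetwork(prox, dist, [r0, r1, r1], [-1, 0, 0])


def _bin4() -> VascularNetwork:
    """Symmetric depth-4 binary tree: 15 segments, 8 terminals.

    Level lengths 8, 4, 2, 1 mm; radii halve per Murray gamma=3 each level;
    branches alternate the x and y planes so no two segments overlap.
    """
    prox, dist, radius, parent = [], [], [], []

    def grow(p_idx, start, level):
        L = 2.0 ** (3 - level)
        r = 1.0 * 2.0 ** (-level / 3.0)
        axis = 0 if level % 2 == 1 else 1
        for sgn in (+1.0, -1.0) if level > 0 else (0.0,):
            d = np.zeros(3)
            d[2] = 0.8 * L if level > 0 else L
            if level > 0:
                d[axis] = sgn * 0.6 * L
            end = start + d
            prox.append(start.copy())
            dist.append(end)
            radius.append(r)
            parent.append(p_idx)
            idx = len(prox) - 1
            if level < 3:
                grow(idx, end, level + 1)

    grow(-1, np.zeros(3), 0)
    return VascularNetwork(np.asarray(prox), np.asarray(dist),
                           np.asarray(radius), np.asarray(parent))


def make_fixture(name: str):
    """Return a named deterministic fixture object.

    Known names: ``y3``, ``bin4``, ``cco200-seed<k>``, ``cube-mesh-<n>``.
    """
    if name == "y3":
        return _y3()
    if name == "bin4":
        return _bin4()
    if name.startswith("cco200-seed"):
        seed = int(name.removeprefix("cco200-seed"))
        return generate_cco_tree(Box.cube(100.0), 200, 3.0, seed=seed)
    if name.startswith("cube-mesh-"):
        n = int(name.removeprefix("cube-mesh-"))
        return build_cube_mesh(n, 1.0)
    raise KeyError(f"unknown fixture {name!r}")


@dataclass
class RunConfig:
    """Declarative single-run pipeline configuration."""

    out_dir: str = "runs/out"
    tree_source: str = "generate"          # or "file"
    tree_file: str | None = None
    domain_size_mm: float = 100.0
    n_terminals: int = 200
    inlet_radius_mm: float = 3.0
    seed: int = 1
    pin_mmhg: float = 100.0
    pout_mmhg: float = 0.0
    mu: float = 0.004
    mesh_n: int = 4
    rev_radius_mm: float = 5.0
    nc: int = 2
    model: str = "II"
    material: MaterialParams = field(default_factory=MaterialParams)
    solver: SolverConfig = field(default_factory=SolverConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mat = MaterialParams(**raw.pop("material", {}))
        sol = SolverConfig(**raw.pop("solver", {}))
        return cls(material=mat, solver=sol, **raw)

    def validate_inputs(self) -> None:
        if self.tree_source == "file":
            if not self.tree_file or not Path(self.tree_file).exists():
                raise FileNotFoundError(f"tree file not found: {self.tree_file}")
        elif self.tree_source != "generate":
            raise ValueError(f"unknown tree_source {self.tree_source!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the five pipeline stages, writing artifacts + manifest.

    Returns the artifact directory.  Reruns with the same config reproduce
    identical checksums.
    """
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _config_dict(config), "version": __version__,
                "python": platform.python_version(), "stages": {}}

    def record(stage: str, path: Path):
        manifest["stages"][stage] = {"file": path.name, "sha256": _sha256(path)}

    # 1. tree
    if config.tree_source == "generate":
        tree = generate_cco_tree(Box.cube(config.domain_size_mm),
                                 config.n_terminals, config.inlet_radius_mm,
                                 seed=split_seed(config.seed, "cco"))
    else:
        tree = read_segment_table(config.tree_file)
    tree_path = out / "tree.csv"
    write_segment_table(tree, tree_path)
    record("generate", tree_path)

    # 2. network flow
    bcs = FlowBCs.from_mmhg(config.pin_mmhg, config.pout_mmhg, config.mu)
    flow = solve_poiseuille(tree, bcs)
    flow_path = out / "flow.csv"
    flow.to_dataframe(tree).to_csv(flow_path, index=False, float_format="%.17g")
    record("flow", flow_path)

    # 3. parameterization
    mesh = build_cube_mesh(config.mesh_n, config.domain_size_mm)
    labels = hierarchy_parameters(tree)
    scheme = partition_compartments(labels, tree.radius, config.nc)
    comp = assign_compartments(tree, scheme, labels)
    rev = REVSpec(radius=config.rev_radius_mm)
    fields = compute_porous_fields(tree, flow, comp, config.nc, mesh.centroids,
                                   rev, model=config.model, mu=config.mu,
                                   domain_volume=mesh.total_volume)
    fields_path = out / "fields.vtk"
    cell_data = {f"phi_{i + 1}": fields.phi0[:, i] for i in range(config.nc)}
    cell_data |= {f"K_{i + 1}": fields.K0[:, i] for i in range(config.nc)}
    cell_data |= {"p1bar": fields.p1bar, "Sext": fields.S_ext}
    write_vtk_mesh(mesh, fields_path, cell_data=cell_data)
    record("parameterize", fields_path)

    # 4. FEM solve
    state, info = newton_solve(mesh, fields, config.material, config.solver)
    sol_path = out / "solution.vtk"
    write_vtk_mesh(mesh, sol_path,
                   point_data={"u": state.u, "p": state.p} |
                   {f"m_star_{i + 2}": state.m_star[:, i]
                    for i in range(state.m_star.shape[1])})
    record("solve", sol_path)

    # 5. validation
    perr, n_v = _perr_for_solution(state, fields, tree, flow, comp, mesh,
                                   config.material,
                                   mmhg_to_pa(config.pin_mmhg))
    report = {"Perr": perr, "n_vessels": n_v,
              "newton_iterations": info["iterations"],
              "inlet_flow_mm3_s": flow.inlet_flow,
              "zeta_crit": scheme.zeta_crit.tolist()}
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    record("validate", report_path)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["material"] = {k: v for k, v in asdict(config.material).items()}
    d["solver"] = asdict(config.solver)
    return d
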