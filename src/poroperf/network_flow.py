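"""Steady Poiseuille flow on the discrete vascular tree.

Each segment is a Poiseuille resistor with conductance g = pi r^4 / (8 mu l);
nodal pressures solve the sparse graph Laplacian with Dirichlet pressure pin
at the inlet node and pout at every unblocked terminal outlet.  Blocked
segments are removed from the system entirely (they carry exactly zero flow).

Node numbering: node i (0 <= i < n_segments) is the distal endpoint of
segment i; node n_segments is the inlet (the root's proximal endpoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .units import mmhg_to_pa
from .vasculature import VascularNetwork

__all__ = [
    "FlowBCs",
    "NetworkFlowSolution",
    "segment_conductance",
    "solve_poiseuille",
    "conservation_report",
]


@dataclass(frozen=True)
class FlowBCs:
    """Pressure boundary conditions and blood viscosity (mm-Pa-s units)."""

    pin: float
    pout: float = 0.0
    mu: float = 0.004

    def __post_init__(self) -> None:
        if self.pin <= self.pout:
            raise ValueError("inlet pressure must exceed outlet pressure")
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")

    @classmethod
    def from_mmhg(cls, pin_mmhg: float = 100.0, pout_mmhg: float = 0.0,
                  mu: float = 0.004) -> "FlowBCs":
        return cls(pin=mmhg_to_pa(pin_mmhg), pout=mmhg_to_pa(pout_mmhg), mu=mu)


@dataclass
class NetworkFlowSolution:
    """Per-segment flows (mm^3/s, positive proximal->distal) and pressures (Pa)."""

    q: np.ndarray
    p_node: np.ndarray        # nodal pressures; node i = distal end of segment i
    p_prox: np.ndarray        # per-segment proximal pressure
    p_dist: np.ndarray        # per-segment distal pressure
    bcs: FlowBCs

    @property
    def p_seg_mean(self) -> np.ndarray:
        """Mean segment pressure (average of the endpoint pressures)."""
        return 0.5 * (self.p_prox + self.p_dist)

    _inlet: float = 0.0

    @property
    def inlet_flow(self) -> float:
        """Flow through the root segment, mm^3/s."""
        return self._inlet

    def to_dataframe(self, network: VascularNetwork) -> pd.DataFrame:
        return pd.DataFrame({
            "segment_id": network.ids,
            "q_mm3_s": self.q,
            "p_prox_pa": self.p_prox,
            "p_dist_pa": self.p_dist,
            "p_mean_pa": self.p_seg_mean,
        })


def segment_conductance(radius: float, length: float, mu: float) -> float:
    """Poiseuille conductance g = pi r^4 / (8 mu l) in mm^3/(Pa s)."""
    if np.any(np.asarray(radius) <= 0) or np.any(np.asarray(length) <= 0) or mu <= 0:
        raise ValueError("radius, length and viscosity must be positive")
    return np.pi * np.asarray(radius) ** 4 / (8.0 * mu * np.asarray(length))


def solve_poiseuille(network: VascularNetwork, bcs: FlowBCs,
                     dense: bool = False) -> NetworkFlowSolution:
    """Solve for nodal pressures and segment flows on the perfused subtree.

    Parameters
    ----------
    dense : solve with a dense LU instead of the sparse factorization.
        Intended as the brute-force cross-check on small trees.
    """
    n = network.n_segments
    root = network.root_id
    inlet_node = n
    g = np.asarray(segment_conductance(network.radius, network.lengths, bcs.mu))

    open_seg = ~network.blocked
    # blocked subtrees must not detach any open segment from the root
    for i in np.flatnonzero(open_seg):
        p = network.parent[i]
        if p >= 0 and not open_seg[p]:
            raise ValueError("open segment hangs below a blocked segment")

    term = network.unblocked_terminals()
    prox_node = np.where(network.parent >= 0, network.parent, inlet_node)

    dirichlet = np.zeros(n + 1, dtype=bool)
    p_bc = np.zeros(n + 1)
    dirichlet[inlet_node] = True
    p_bc[inlet_node] = bcs.pin
    dirichlet[term] = True
    p_bc[term] = bcs.pout

    # assemble Laplacian over open segments
    segs = np.flatnonzero(open_seg)
    rows = np.concatenate([prox_node[segs], segs, prox_node[segs], segs])
    cols = np.concatenate([prox_node[segs], segs, segs, prox_node[segs]])
    vals = np.concatenate([g[segs], g[segs], -g[segs], -g[segs]])
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n + 1, n + 1))

    free = np.flatnonzero(~dirichlet & np.concatenate([open_seg, [True]])[: n + 1])
    # nodes of blocked segments keep pressure 0 (unused)
    p_node = p_bc.copy()
    if len(free):
        A = L[free][:, free]
        b = -L[free][:, np.flatnonzero(dirichlet)] @ p_bc[dirichlet]
        if dense:
            sol = np.linalg.solve(A.toarray(), b)
        else:
            sol = spla.spsolve(A.tocsc(), b)
        if not np.all(np.isfinite(sol)):
            raise ValueError("singular Poiseuille system (disconnected perfused subtree)")
        p_node[free] = sol

    p_prox = p_node[prox_node]
    p_dist = p_node[np.arange(n)]
    q = g * (p_prox - p_dist)
    q[~open_seg] = 0.0
    p_prox = np.where(open_seg, p_prox, 0.0)
    p_dist = np.where(open_seg, p_dist, 0.0)
    sol = NetworkFlowSolution(q=q, p_node=p_node, p_prox=p_prox, p_dist=p_dist, bcs=bcs)
    sol._inlet = float(q[root])
    return sol


def conservation_report(solution: NetworkFlowSolution, network: VascularNetwork,
                        floor: float = 1e-30) -> float:
    """Max relative nodal flow imbalance over interior (non-Dirichlet) nodes.

    Interior nodes are distal endpoints of open non-terminal segments; at
    each, inflow q_parent_segment must equal the summed child outflows.
    """
    n = network.n_segments
    open_seg = ~network.blocked
    term = np.zeros(n, dtype=bool)
    term[network.unblocked_terminals()] = True
    inflow = solution.q.copy()
    outflow = np.zeros(n)
    for i in np.flatnonzero(open_seg):
        p = network.parent[i]
        if p >= 0:
            outflow[p] += solution.q[i]
    interior = open_seg & ~term
    if not np.any(interior):
        return 0.0
    imb = np.abs(inflow[interior] - outflow[interior])
    scale = np.maximum(np.abs(inflow[interior]), floor)
    return float(np.max(imb / scale))
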