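"""REV homogenization: discrete vessels -> continuum porous fields.

Every continuum evaluation point (element centroids of the FEM mesh) gets,
per compartment i: a porosity phi0_i = sum(pi r^2 l)/V_R, a permeability
tensor K0_i (Models I/II/III below), inter-compartment coupling constants
beta_{k,i,0}, the prescribed first-compartment pressure p1bar, and the
terminal sink density S_ext of the last compartment.  The REV is a sphere of
radius rR around the point; by default a segment belongs to the REV iff its
midpoint is inside (``midpoint`` rule), optionally with exact segment-sphere
clipping (``clipped`` rule).  Blocked segments never contribute.

Permeability models:
  I   heterogeneous anisotropic: K = sum pi r^4 l (t x t) / (8 mu V_R)
  II  heterogeneous isotropic:   K = [sum pi r^4 l / (8 mu V_R)] I
  III homogeneous isotropic:     K = [sum over whole compartment / (8 mu V_T)] I

Coupling: beta_{k,i,0}(X) = Q_{k,i}(X) / (V_R (pbar_k - pbar_i)) where
Q_{k,i} sums Poiseuille flows through junctions where a compartment-k segment
feeds a compartment-i one (both segments REV members) and pbar is the
vessel-volume-weighted mean Poiseuille pressure of the compartment in the
REV.  Negative or undefined values are clamped to zero (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .network_flow import NetworkFlowSolution
from .vasculature import CompartmentScheme, VascularNetwork

__all__ = ["REVSpec", "REVMembership", "PorousFields", "rev_members",
           "build_membership", "porosity_field", "permeability_field",
           "coupling_field", "boundary_fields", "compute_porous_fields"]

log = logging.getLogger(__name__)

PERMEABILITY_MODELS = ("I", "II", "III")


@dataclass(frozen=True)
class REVSpec:
    """Spherical representative elementary volume."""

    radius: float                      # rR, mm
    inclusion_rule: str = "midpoint"   # or "clipped"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("REV radius must be positive")
        if self.inclusion_rule not in ("midpoint", "clipped"):
            raise ValueError(f"unknown inclusion rule {self.inclusion_rule!r}")

    @property
    def volume(self) -> float:
        """V_R = 4/3 pi rR^3, mm^3."""
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass
class REVMembership:
    """Sparse (point, segment) membership with effective lengths.

    ``pt``, ``seg``, ``eff_len`` are parallel pair arrays; ``matrix`` is the
    boolean CSR incidence (n_points x n_segments).  Reusable across models
    and compartment counts for a fixed (network, points, REV).
    """

    n_points: int
    n_segments: int
    pt: np.ndarray
    seg: np.ndarray
    eff_len: np.ndarray
    matrix: sp.csr_matrix


def _clip_lengths(points, prox, dist, rR):
    """Length of each segment's intersection with spheres centred at points.

    ``points`` (n,3) paired with segment rows (n,3): returns (n,) lengths.
    """
    d = dist - prox
    L = np.linalg.norm(d, axis=1)
    u = d / np.maximum(L[:, None], 1e-30)
    w = prox - points
    b = np.einsum("ij,ij->i", u, w)
    c = np.einsum("ij,ij->i", w, w) - rR * rR
    disc = b * b - c
    t0 = np.where(disc > 0, -b - np.sqrt(np.maximum(disc, 0.0)), np.inf)
    t1 = np.where(disc > 0, -b + np.sqrt(np.maximum(disc, 0.0)), -np.inf)
    lo = np.clip(t0, 0.0, L)
    hi = np.clip(t1, 0.0, L)
    return np.maximum(hi - lo, 0.0)


def build_membership(network: VascularNetwork, points: np.ndarray,
                     rev: REVSpec) -> REVMembership:
    """Compute (point, segment) REV membership pairs for all points at once."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_pts, n_seg = len(points), network.n_segments
    open_idx = np.flatnonzero(~network.blocked)
    mids = network.midpoints[open_idx]
    lens = network.lengths[open_idx]
    tree = cKDTree(mids)
    if rev.inclusion_rule == "midpoint":
        lists = tree.query_ball_point(points, rev.radius)
        pt = np.repeat(np.arange(n_pts), [len(l) for l in lists])
        seg = open_idx[np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
                       if len(pt) else np.empty(0, dtype=np.int64)]
        eff = network.lengths[seg]
    else:
        reach = rev.radius + 0.5 * float(lens.max(initial=0.0))
        lists = tree.query_ball_point(points, reach)
        pt = np.repeat(np.arange(n_pts), [len(l) for l in lists])
        cand = open_idx[np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
                        if len(pt) else np.empty(0, dtype=np.int64)]
        eff = _clip_lengths(points[pt], network.proximal[cand],
                            network.distal[cand], rev.radius)
        keep = eff > 0.0
        pt, seg, eff = pt[keep], cand[keep], eff[keep]
    mat = sp.csr_matrix((np.ones(len(pt)), (pt, seg)), shape=(n_pts, n_seg))
    return REVMembership(n_points=n_pts, n_segments=n_seg, pt=pt, seg=seg,
                         eff_len=eff, matrix=mat)


def rev_members(network: VascularNetwork, X, rev: REVSpec,
                comp: np.ndarray | None = None,
                scheme: CompartmentScheme | None = None):
    """Per-compartment member lists [(segment_index, effective_length), ...]
    for a single REV centred at X.  Blocked segments are never members."""
    from .vasculature import hierarchy_parameters
    if comp is None:
        if scheme is None:
            raise ValueError("provide either comp labels or a scheme")
        comp = scheme.assign(hierarchy_parameters(network).zeta)
    mem = build_membership(network, np.asarray(X, dtype=float)[None, :], rev)
    nc = int(comp.max())
    out = {i: [] for i in range(1, nc + 1)}
    for s, el in zip(mem.seg, mem.eff_len):
        out[int(comp[s])].append((int(s), float(el)))
    return out


def _compartment_sums(mem: REVMembership, comp: np.ndarray, nc: int,
                      weights: np.ndarray) -> np.ndarray:
    """Sum pair weights into (n_points, nc) bins by segment compartment."""
    flat = mem.pt * nc + (comp[mem.seg] - 1)
    return np.bincount(flat, weights=weights,
                       minlength=mem.n_points * nc).reshape(mem.n_points, nc)


def porosity_field(network: VascularNetwork, comp: np.ndarray, nc: int,
                   points, rev: REVSpec,
                   mem: REVMembership | None = None) -> np.ndarray:
    """phi0_i(X) = sum_j pi r_j^2 l_j / V_R over compartment-i REV members."""
    if mem is None:
        mem = build_membership(network, points, rev)
    w = np.pi * network.radius[mem.seg] ** 2 * mem.eff_len
    return _compartment_sums(mem, comp, nc, w) / rev.volume


def permeability_field(network: VascularNetwork, comp: np.ndarray, nc: int,
                       points, rev: REVSpec, model: str, mu: float,
                       mem: REVMembership | None = None,
                       domain_volume: float | None = None) -> np.ndarray:
    """Per-point, per-compartment permeability tensors, (n_pts, nc, 3, 3)."""
    if model not in PERMEABILITY_MODELS:
        raise ValueError(f"unknown permeability model {model!r}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_pts = len(points)
    if model == "III":
        if domain_volume is None:
            raise ValueError("Model III needs the total domain volume V_T")
        open_seg = np.flatnonzero(~network.blocked)
        w = np.pi * network.radius[open_seg] ** 4 * network.lengths[open_seg] \
            / (8.0 * mu * domain_volume)
        scal = np.bincount(comp[open_seg] - 1, weights=w, minlength=nc)
        K = np.einsum("i,kl->ikl", scal, np.eye(3))
        return np.broadcast_to(K, (n_pts, nc, 3, 3)).copy()
    if mem is None:
        mem = build_membership(network, points, rev)
    w = np.pi * network.radius[mem.seg] ** 4 * mem.eff_len / (8.0 * mu * rev.volume)
    if model == "II":
        scal = _compartment_sums(mem, comp, nc, w)
        return np.einsum("pi,kl->pikl", scal, np.eye(3))
    t = network.directions[mem.seg]
    outer = np.einsum("jk,jl->jkl", t, t)
    K = np.zeros((n_pts, nc, 3, 3))
    flat = mem.pt * nc + (comp[mem.seg] - 1)
    for a in range(3):
        for b in range(a, 3):
            acc = np.bincount(flat, weights=w * outer[:, a, b],
                              minlength=n_pts * nc).reshape(n_pts, nc)
            K[:, :, a, b] = acc
            if b != a:
                K[:, :, b, a] = acc
    return K


def _mean_pressures(network, flow, mem, comp, nc, rev, normalization):
    """Volume-weighted mean segment pressures per (point, compartment).

    Returns (pbar, has) where ``has`` marks compartments with members.
    ``normalization='mean'`` divides by the compartment vessel volume in the
    REV (pressure units, default); ``'printed'`` divides by V_R as typeset.
    """
    w = np.pi * network.radius[mem.seg] ** 2 * mem.eff_len
    p = flow.p_seg_mean[mem.seg]
    num = _compartment_sums(mem, comp, nc, w * p)
    den = _compartment_sums(mem, comp, nc, w)
    has = den > 0
    if normalization == "printed":
        return num / rev.volume, has
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(has, num / np.where(has, den, 1.0), 0.0)
    return pbar, has


def _junctions(network: VascularNetwork, comp: np.ndarray):
    """Inter-compartment junctions: child segments whose compartment differs
    from their (open) parent's.  Returns (child_idx, parent_idx)."""
    child = np.flatnonzero((network.parent >= 0) & ~network.blocked)
    child = child[~network.blocked[network.parent[child]]]
    parent = network.parent[child]
    diff = comp[child] != comp[parent]
    return child[diff], parent[diff]


def coupling_field(network: VascularNetwork, flow: NetworkFlowSolution,
                   comp: np.ndarray, nc: int, points, rev: REVSpec, model: str,
                   mem: REVMembership | None = None,
                   normalization: str = "mean") -> np.ndarray:
    """beta_{k,i,0} per point, (n_pts, nc, nc), symmetric, clamped >= 0."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_pts = len(points)
    beta = np.zeros((n_pts, nc, nc))
    child, parent = _junctions(network, comp)
    if len(child) == 0:
        return beta
    qj = flow.q[child]
    pairs = {(int(k), int(i)) for k, i in zip(comp[parent], comp[child])}
    if model == "III":
        # domain totals and domain-averaged pressures (single uniform value)
        open_seg = np.flatnonzero(~network.blocked)
        w_all = np.pi * network.radius[open_seg] ** 2 * network.lengths[open_seg]
        p_all = flow.p_seg_mean[open_seg]
        num = np.bincount(comp[open_seg] - 1, weights=w_all * p_all, minlength=nc)
        den = np.bincount(comp[open_seg] - 1, weights=w_all, minlength=nc)
        if normalization == "printed":
            pbar_avg = num / rev.volume
        else:
            pbar_avg = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        for (k, i) in sorted(pairs):
            sel = (comp[parent] == k) & (comp[child] == i)
            Q = float(qj[sel].sum())
            dp = pbar_avg[k - 1] - pbar_avg[i - 1]
            val = Q / (rev.volume * dp) if dp != 0.0 else 0.0
            if val < 0.0:
                log.warning("clamping negative beta(%d,%d)=%.3e to 0", k, i, val)
                val = 0.0
            beta[:, k - 1, i - 1] = beta[:, i - 1, k - 1] = val
        return beta
    if mem is None:
        mem = build_membership(network, points, rev)
    pbar, has = _mean_pressures(network, flow, mem, comp, nc, rev, normalization)
    Mp = mem.matrix[:, parent]
    Mc = mem.matrix[:, child]
    both = Mp.multiply(Mc).tocsr()          # (n_pts, n_junctions), 1 where both in REV
    n_clamped = 0
    for (k, i) in sorted(pairs):
        sel = np.flatnonzero((comp[parent] == k) & (comp[child] == i))
        Q = np.asarray(both[:, sel] @ qj[sel]).ravel()
        dp = pbar[:, k - 1] - pbar[:, i - 1]
        ok = has[:, k - 1] & has[:, i - 1] & (dp != 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(ok, Q / (rev.volume * np.where(ok, dp, 1.0)), 0.0)
        n_clamped += int(np.count_nonzero(val < 0))
        val = np.maximum(val, 0.0)
        beta[:, k - 1, i - 1] = beta[:, i - 1, k - 1] = val
    if n_clamped:
        log.warning("clamped %d negative/undefined coupling values to 0", n_clamped)
    return beta


def boundary_fields(network: VascularNetwork, flow: NetworkFlowSolution,
                    comp: np.ndarray, nc: int, points, rev: REVSpec,
                    mem: REVMembership | None = None,
                    normalization: str = "mean"):
    """(p1bar, S_ext) per point.

    p1bar is the compartment-1 volume-weighted mean Poiseuille pressure in
    the REV; S_ext is the terminal sink density -(1/V_R) sum of outflows of
    unblocked terminal segments that are REV members (under the same
    inclusion rule as every other field, so a sink only appears where the
    terminal vessels themselves contribute porosity and permeability; under
    the clipped rule a partially included terminal sinks proportionally).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if mem is None:
        mem = build_membership(network, points, rev)
    pbar, _ = _mean_pressures(network, flow, mem, comp, nc, rev, normalization)
    p1bar = pbar[:, 0]
    is_term = np.zeros(network.n_segments, dtype=bool)
    is_term[network.unblocked_terminals()] = True
    sel = is_term[mem.seg]
    frac = mem.eff_len[sel] / network.lengths[mem.seg[sel]]
    S = -np.bincount(mem.pt[sel], weights=flow.q[mem.seg[sel]] * frac,
                     minlength=len(points)) / rev.volume
    return p1bar, S


def junction_flow_field(network: VascularNetwork, flow: NetworkFlowSolution,
                        comp: np.ndarray, points, rev: REVSpec, k: int, i: int,
                        mem: REVMembership | None = None) -> np.ndarray:
    """Q_{k,i}(X): summed Poiseuille flow through k->i junctions whose two
    segments are both REV members, per evaluation point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if mem is None:
        mem = build_membership(network, points, rev)
    child, parent = _junctions(network, comp)
    sel = np.flatnonzero((comp[parent] == k) & (comp[child] == i))
    if len(sel) == 0:
        return np.zeros(len(points))
    both = mem.matrix[:, parent[sel]].multiply(mem.matrix[:, child[sel]])
    return np.asarray(both @ flow.q[child[sel]]).ravel()


@dataclass
class PorousFields:
    """All continuum porous fields at the evaluation points.

    Arrays are indexed by evaluation point (first axis) and 0-based
    compartment (second axis where present); compartment i of the theory is
    index i-1 here.
    """

    points: np.ndarray          # (n_pts, 3)
    nc: int
    rev: REVSpec
    model: str
    mu: float
    phi0: np.ndarray            # (n_pts, nc)
    K0: np.ndarray              # (n_pts, nc, 3, 3), mm^2/(Pa s)
    beta0: np.ndarray           # (n_pts, nc, nc), 1/(Pa s), symmetric
    p1bar: np.ndarray           # (n_pts,), Pa
    S_ext: np.ndarray           # (n_pts,), 1/s (sink: <= 0)
    pbar: np.ndarray | None = None  # (n_pts, nc) REV-mean Poiseuille pressures
    kappa_min: float = 1e-10

    def floored_K(self, i: int) -> np.ndarray:
        """K0 of (1-based) compartment i with the isotropic floor added.

        The floor keeps the Darcy operator nonsingular where a compartment
        has no vessels and regularizes the rank-deficient tensors the
        anisotropic model produces in REVs holding one or two near-parallel
        vessels; at 4+ orders of magnitude below typical vessel-bearing
        permeabilities it does not affect the physical contrast.
        """
        return self.K0[:, i - 1] + self.kappa_min * np.eye(3)

    def floored_phi0(self, i: int, phi_floor: float) -> np.ndarray:
        return np.maximum(self.phi0[:, i - 1], phi_floor)


def compute_porous_fields(network: VascularNetwork, flow: NetworkFlowSolution,
                          comp: np.ndarray, nc: int, points, rev: REVSpec,
                          model: str = "I", mu: float = 0.004,
                          domain_volume: float | None = None,
                          mem: REVMembership | None = None,
                          kappa_min: float = 1e-10,
                          normalization: str = "mean") -> PorousFields:
    """Build all porous fields in one pass (membership computed once)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if mem is None:
        mem = build_membership(network, points, rev)
    phi0 = porosity_field(network, comp, nc, points, rev, mem=mem)
    K0 = permeability_field(network, comp, nc, points, rev, model, mu,
                            mem=mem, domain_volume=domain_volume)
    beta0 = coupling_field(network, flow, comp, nc, points, rev, model,
                           mem=mem, normalization=normalization)
    p1bar, S_ext = boundary_fields(network, flow, comp, nc, points, rev,
                                   mem=mem, normalization=normalization)
    pbar, _ = _mean_pressures(network, flow, mem, comp, nc, rev, normalization)
    return PorousFields(points=points, nc=nc, rev=rev, model=model, mu=mu,
                        phi0=phi0, K0=K0, beta0=beta0, p1bar=p1bar,
                        S_ext=S_ext, pbar=pbar, kappa_min=kappa_min)
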