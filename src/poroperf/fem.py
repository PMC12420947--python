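"""Stabilized P1 finite elements for the steady multicompartment problem.

Unknowns are the nodal displacement u, the skeleton pressure p enforcing
incompressibility J - 1 = sum_i m*_i, and the added pore volume m*_i of every
solved compartment i = 2..nc (compartment 1 is data: its pore pressure is
the prescribed field p1bar).  Per solved compartment the steady mass balance

    div( K00_i grad p + K0m_i grad m*_i ) + S_i = 0,
    S_i = S_i^ext + sum_{k != i} beta_{k,i,0} (p_k^pore - p_i^pore),

couples to momentum div(F S) = 0 and the stabilized incompressibility
residual; equal-order P1-P1 pairs violate the LBB condition, which is
repaired with the fine-scale pressure-gradient term

    sum_K int_K u' . (J F^{-T} grad ptilde),   u' = -(alpha h^2 / 2G) F^{-T} grad p.

Natural boundary conditions (zero flux, zero traction) are imposed by
dropping the boundary terms; rigid modes of the traction-free momentum
equation are pinned at six well-separated displacement components.

Discrete conventions (these define the exact Jacobian): displacement-derived
quantities (F, J, K00) are constant per element; the K0m coefficient uses
dp/dm* at the element-mean m*_i; source and incompressibility volume terms
use the 4-point second-order quadrature rule.  The Jacobian is the exact
analytic linearization of this discrete residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import MaterialParams, pore_fluid_pressure
from .homogenization import PorousFields
from .mesh import QUAD_BARY, TetMesh

__all__ = ["SolverConfig", "SolutionState", "PoroelasticSystem",
           "assemble_system", "newton_solve", "NewtonDivergenceError",
           "darcy_mms_check", "ManufacturedDarcy", "solve_darcy_p1"]

log = logging.getLogger(__name__)

_EYE = np.eye(3)
# int N_a N_b over the element as a fraction of its volume (4-pt rule, exact)
_MASS44 = np.einsum("qa,qb->ab", QUAD_BARY, QUAD_BARY) / 4.0


class NewtonDivergenceError(RuntimeError):
    pass


def initial_state_from_poiseuille(mesh: TetMesh, fields: PorousFields,
                                  params: MaterialParams) -> SolutionState:
    """Warm start: invert the tube law against the REV-mean Poiseuille
    pressures of each solved compartment, so m* starts near equilibrium.

    Solves p_PV(m*) + p_c(m*) = pbar_i per node with a few damped Newton
    steps on the monotone scalar law; nodes without vessel data start at 0.
    """
    ns = fields.nc - 1
    state = SolutionState.zeros(mesh.n_nodes, ns)
    if fields.pbar is None:
        return state
    phi0n = nodal_reference_porosity(mesh, fields, params)
    # nodal volume-weighted mean of the compartment pressures
    num = np.zeros((mesh.n_nodes, ns))
    den = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(num, mesh.tets[:, a],
                  fields.pbar[:, 1:] * mesh.volumes[:, None])
        np.add.at(den, mesh.tets[:, a], mesh.volumes)
    target = num / den[:, None]
    w = np.zeros((mesh.n_nodes, ns))
    for _ in range(40):
        v = phi0n * np.exp(w)
        pp = pore_fluid_pressure(v - phi0n, phi0n, params)
        f = pp.total - target
        df_dw = pp.dp_dm * v
        w = np.clip(w - np.clip(f / np.maximum(df_dw, 1e-30), -0.5, 0.5),
                    np.log(1e-2), np.log(0.2 / phi0n))
    state.m_star = phi0n * np.expm1(w)
    return state


def nodal_reference_porosity(mesh: TetMesh, fields: PorousFields,
                             params: MaterialParams) -> np.ndarray:
    """Solved-compartment reference porosities as a nodal P1 field, (N, ns).

    Volume-weighted average of the element-wise REV porosities over the
    elements adjacent to each node, floored at ``params.phi_floor``.
    """
    ns = fields.nc - 1
    num = np.zeros((mesh.n_nodes, ns))
    den = np.zeros(mesh.n_nodes)
    phi_e = fields.phi0[:, 1:]                        # solved compartments
    for a in range(4):
        np.add.at(num, mesh.tets[:, a], phi_e * mesh.volumes[:, None])
        np.add.at(den, mesh.tets[:, a], mesh.volumes)
    return np.maximum(num / den[:, None], params.phi_floor)


@dataclass
class SolverConfig:
    """Newton, pseudo-transient continuation and stabilization settings.

    A direct damped Newton solve is attempted first; on a stall the solver
    falls back to implicit-Euler pseudo-time marching of the pore-volume
    equations (``ptc_*`` settings) until the steady Newton endgame succeeds.
    """

    newton_tol: float = 1e-8
    max_newton: int = 30           # iteration cap of a single Newton phase
    alpha: float = 0.2
    rigid_mode_handling: str = "pin6"
    backtrack_max: int = 6
    ptc_dtau0: float = 1e-3        # initial pseudo-timestep, s
    max_sweeps: int = 40           # staggered mass/elasticity sweeps
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")
        if self.rigid_mode_handling not in ("pin6",):
            raise ValueError("only 'pin6' rigid-mode handling is implemented")


@dataclass
class SolutionState:
    """Nodal solution: u (N,3) mm, p (N,) Pa, m_star (N, nc-1) for i=2..nc."""

    u: np.ndarray
    p: np.ndarray
    m_star: np.ndarray

    @classmethod
    def zeros(cls, n_nodes: int, n_solved: int) -> "SolutionState":
        return cls(u=np.zeros((n_nodes, 3)), p=np.zeros(n_nodes),
                   m_star=np.zeros((n_nodes, n_solved)))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.u.ravel(), self.p,
                               self.m_star.T.ravel()])

    @classmethod
    def unpack(cls, x: np.ndarray, n_nodes: int, n_solved: int) -> "SolutionState":
        u = x[: 3 * n_nodes].reshape(n_nodes, 3)
        p = x[3 * n_nodes: 4 * n_nodes]
        m = x[4 * n_nodes:].reshape(n_solved, n_nodes).T
        return cls(u=u.copy(), p=p.copy(), m_star=m.copy())


class PoroelasticSystem:
    """Element-parallel residual/Jacobian assembly for one mesh + field set."""

    def __init__(self, mesh: TetMesh, fields: PorousFields,
                 params: MaterialParams, config: SolverConfig | None = None):
        if fields.nc < 2:
            raise ValueError("need at least two compartments (one solved)")
        if len(fields.points) != mesh.n_elements:
            raise ValueError("fields must be evaluated at the element centroids")
        self.mesh = mesh
        self.fields = fields
        self.params = params
        self.config = config or SolverConfig()
        self.nc = fields.nc
        self.ns = fields.nc - 1            # solved compartments 2..nc
        self.N = mesh.n_nodes
        self.E = mesh.n_elements
        self.ndof = (4 + self.ns) * self.N

        self.B = mesh.grads                               # (E,4,3)
        self.V = mesh.volumes                             # (E,)
        self.conn = mesh.tets                             # (E,4)
        self.cstab = self.config.alpha * mesh.h**2 / (2.0 * params.G)

        self.K0 = np.stack([fields.floored_K(i) for i in range(2, self.nc + 1)],
                           axis=1)                        # (E,ns,3,3)
        self.beta = fields.beta0                          # (E,nc,nc)
        self.p1bar = fields.p1bar
        self.S_ext = fields.S_ext
        self._check_anchor()

        # Reference porosity enters the tube law as a nodal P1 field (volume-
        # weighted average of the element values, floored).  With nodal phi0,
        # v = m* + phi0 at any quadrature point is a convex combination of
        # nodal values, so keeping nodal v positive keeps every quadrature
        # point admissible - element-wise phi0 would instead give one shared
        # nodal m* conflicting barrier positions in adjacent elements.
        self.phi0_node = nodal_reference_porosity(mesh, fields, params)  # (N,ns)
        self.phi0_e = self.phi0_node[self.conn]           # (E,4,ns)
        self.phi0_bar = self.phi0_e.mean(axis=1)          # (E,ns)

        # m*-dofs at nodes none of whose elements hold genuine compartment
        # vessels are fixed at zero: there is no pore fluid to add there, and
        # their equations (floor permeability only) would be near-singular
        active_elem = np.trace(fields.K0[:, 1:], axis1=2, axis2=3).T > 0  # (ns,E)
        active_node = np.zeros((self.ns, self.N), dtype=bool)
        for s in range(self.ns):
            active_node[s, np.unique(self.conn[active_elem[s]])] = True
        self.inactive_mdofs = np.concatenate(
            [4 * self.N + s * self.N + np.flatnonzero(~active_node[s])
             for s in range(self.ns)]) if self.ns else np.empty(0, np.int64)

        # global dof indices
        nodes = self.conn
        self.udof = (3 * nodes)[:, :, None] + np.arange(3)[None, None, :]  # (E,4,3)
        self.pdof = 3 * self.N + nodes                                     # (E,4)
        self.mdof = (4 * self.N + np.arange(self.ns)[:, None, None] * self.N
                     + nodes[None])                                        # (ns,E,4)

    def _check_anchor(self) -> None:
        """The Darcy pressure level is anchored through couplings that reach
        compartment 1 (whose pore pressure is prescribed).  Verify every
        solved compartment is connected to compartment 1 in the beta graph."""
        tot = self.beta.sum(axis=0)  # (nc,nc) summed over elements
        reach = {0}
        grew = True
        while grew:
            grew = False
            for i in range(self.nc):
                if i not in reach and any(tot[i, j] > 0 for j in reach):
                    reach.add(i)
                    grew = True
        missing = [i + 1 for i in range(1, self.nc) if i not in reach]
        if missing:
            raise ValueError(
                f"compartments {missing} have no coupling path to compartment 1; "
                "the pressure level would be undetermined")

    # -- kinematics helpers -------------------------------------------------
    def _element_state(self, state: SolutionState):
        u_e = state.u[self.conn]                          # (E,4,3)
        p_e = state.p[self.conn]                          # (E,4)
        m_e = state.m_star[self.conn]                     # (E,4,ns)
        gu = np.einsum("eai,eaJ->eiJ", u_e, self.B)
        F = gu + _EYE
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise FloatingPointError("non-positive J during assembly")
        Fi = np.linalg.inv(F)
        FiT = np.swapaxes(Fi, 1, 2)
        Ci = np.einsum("eMk,eNk->eMN", Fi, Fi)            # F^{-1} F^{-T}
        trC = np.einsum("ekM,ekM->e", F, F)
        gp = np.einsum("ea,eaJ->eJ", p_e, self.B)         # (E,3)
        gm = np.einsum("eas,eaJ->esJ", m_e, self.B)       # (E,ns,3)
        pbar = p_e.mean(axis=1)
        mbar = m_e.mean(axis=1)                           # (E,ns)
        p_q = np.einsum("qa,ea->eq", QUAD_BARY, p_e)      # (E,4)
        m_q = np.einsum("qa,eas->eqs", QUAD_BARY, m_e)    # (E,4,ns)
        return dict(u_e=u_e, p_e=p_e, m_e=m_e, gu=gu, F=F, J=J, Fi=Fi, FiT=FiT,
                    Ci=Ci, trC=trC, gp=gp, gm=gm, pbar=pbar, mbar=mbar,
                    p_q=p_q, m_q=m_q)

    def _pore_quantities(self, st):
        """Tube-law pressure z = p_PV + p_c as a nodal P1 field.

        The flux K0m grad m* = K00 dp/dm grad m* is discretized in Kirchhoff
        form as K00 grad z_h with z_h the P1 interpolant of the nodal tube-law
        pressures: the same continuum operator, but linear in z, which removes
        the double (exp/log) nonlinearity from the discrete mass balance.
        Returns (z_e, dpdm_e, gz, pore_q): nodal values and gradients per
        element plus the quadrature-point pore pressures per compartment.
        """
        ppn = pore_fluid_pressure(st["m_e"], self.phi0_e, self.params)
        z_e = ppn.total                                   # (E,4,ns)
        dpdm_e = ppn.dp_dm                                # (E,4,ns)
        gz = np.einsum("eas,eaJ->esJ", z_e, self.B)       # (E,ns,3)
        z_q = np.einsum("qa,eas->eqs", QUAD_BARY, z_e)
        pore_q = np.empty((self.E, 4, self.nc))
        pore_q[:, :, 0] = self.p1bar[:, None]
        pore_q[:, :, 1:] = st["p_q"][:, :, None] + z_q
        return z_e, dpdm_e, gz, pore_q

    # sink starvation threshold: the terminal sink shuts down smoothly once
    # the local porosity v falls below ~this fraction of its reference value
    # (a collapsed pore space cannot supply the prescribed outflow); in the
    # well-resolved regime v stays near phi0 and the factor is ~1
    _SINK_THETA = 0.05

    def _sink_factor(self, st):
        """Element-wise sink starvation factor sigma in (0,1] and its
        derivative with respect to each nodal m* of the last compartment.

        The porosity ratio s = v/phi0 of the element is summarized by the
        smooth harmonic mean of its four nodal ratios (dominated by the
        smallest): once the pore space collapses at ANY node of an element,
        the whole element's terminal outflow shuts down, so a sink can never
        drain its own supply path without bound.  Returns
        (sigma (E,), dsigma_dm (E,4)).
        """
        phi_a = self.phi0_e[:, :, -1]                       # (E,4)
        v_a = st["m_e"][:, :, -1] + phi_a
        srel = v_a / phi_a
        s_h = 4.0 / np.sum(1.0 / srel, axis=1)              # (E,)
        th2 = self._SINK_THETA**2
        den = s_h * s_h + th2
        sigma = s_h * s_h / den
        dsig_dsh = 2.0 * s_h * th2 / den**2
        # d s_h / d s_a = s_h^2 / (4 s_a^2);  d s_a / d m_a = 1/phi0_a
        dsh_dm = (s_h[:, None] ** 2) / (4.0 * srel**2) / phi_a
        return sigma, dsig_dsh[:, None] * dsh_dm

    def _sources_q(self, pore_q):
        """Inter-compartment exchange S_i at quadrature points, (E,4q,ns).
        The terminal sink is handled separately (nodally lumped)."""
        S = np.zeros((self.E, 4, self.ns))
        for s in range(self.ns):
            i0 = s + 1  # 0-based compartment index
            diff = pore_q - pore_q[:, :, i0][:, :, None]   # p_k - p_i
            S[:, :, s] = np.einsum("ek,eqk->eq", self.beta[:, :, i0], diff)
        return S

    # -- residual -----------------------------------------------------------
    def residual(self, state: SolutionState) -> np.ndarray:
        st = self._element_state(state)
        _, _, gz, pore_q = self._pore_quantities(st)
        sink_sigma, _ = self._sink_factor(st)
        S_q = self._sources_q(pore_q)
        V, B = self.V, self.B
        J, F, FiT, Ci = st["J"], st["F"], st["FiT"], st["Ci"]
        J23 = J ** (-2.0 / 3.0)

        P = (self.params.G * J23[:, None, None]
             * (F - (st["trC"] / 3.0)[:, None, None] * FiT)
             - (st["pbar"] * J)[:, None, None] * FiT)
        R_u = np.einsum("e,emN,eaN->eam", V, P, B)

        vol_q = (J[:, None] - 1.0 - st["m_q"].sum(axis=2))            # (E,4)
        R_p = np.einsum("e,qa,eq->ea", V / 4.0, QUAD_BARY, vol_q)
        # fine-scale pressure-gradient stabilization (alpha h^2 / 2G) J C^-1
        # grad p; its sign is fixed by stability: eliminating p must ADD the
        # penalty B^T C^-1 B to the displacement operator, not subtract it
        R_p += (self.cstab * V * J)[:, None] * np.einsum("eaM,eMN,eN->ea",
                                                         B, Ci, st["gp"])

        K00 = np.einsum("e,eMk,eskl,eNl->esMN", J, st["Fi"], self.K0, st["Fi"])
        w = st["gp"][:, None, :] + gz                                 # (E,ns,3)
        flux = np.einsum("esMN,esN->esM", K00, w)
        R_m = np.einsum("e,eaM,esM->eas", V, B, flux)
        R_m -= np.einsum("e,qa,eqs->eas", V / 4.0, QUAD_BARY, S_q)
        R_m[:, :, -1] -= ((V / 4.0) * self.S_ext * sink_sigma)[:, None]

        R = np.zeros(self.ndof)
        np.add.at(R, self.udof.ravel(), R_u.ravel())
        np.add.at(R, self.pdof.ravel(), R_p.ravel())
        for s in range(self.ns):
            np.add.at(R, self.mdof[s].ravel(), R_m[:, :, s].ravel())
        return R

    # -- frozen-(u,p) mass subsystem ----------------------------------------
    def mass_operator(self, state: SolutionState) -> dict:
        """Geometric pieces of the mass balance at frozen displacement and
        skeleton pressure, cached across the inner mass-Newton iterations."""
        st = self._element_state(state)
        K00 = np.einsum("e,eMk,eskl,eNl->esMN", st["J"], st["Fi"],
                        self.K0, st["Fi"])
        BKB = np.einsum("eaM,esMN,ebN->esab", self.B, K00, self.B)
        BKgp = np.einsum("eaM,esMN,eN->esa", self.B, K00, st["gp"])
        return dict(BKB=BKB, BKgp=BKgp, p_q=st["p_q"])

    def mass_residual(self, m_star: np.ndarray, op: dict) -> np.ndarray:
        """Mass-balance residual rows only, as a flat (ns*N,) vector."""
        m_e = m_star[self.conn]
        ppn = pore_fluid_pressure(m_e, self.phi0_e, self.params)
        z_e = ppn.total
        z_q = np.einsum("qa,eas->eqs", QUAD_BARY, z_e)
        pore_q = np.empty((self.E, 4, self.nc))
        pore_q[:, :, 0] = self.p1bar[:, None]
        pore_q[:, :, 1:] = op["p_q"][:, :, None] + z_q
        S_q = self._sources_q(pore_q)
        sink_sigma, _ = self._sink_factor({"m_e": m_e})
        V = self.V
        R_m = np.einsum("e,esa->eas", V, op["BKgp"]) \
            + np.einsum("e,esab,ebs->eas", V, op["BKB"], z_e)
        R_m -= np.einsum("e,qa,eqs->eas", V / 4.0, QUAD_BARY, S_q)
        R_m[:, :, -1] -= ((V / 4.0) * self.S_ext * sink_sigma)[:, None]
        R = np.zeros(self.ns * self.N)
        for s in range(self.ns):
            np.add.at(R, (self.mdof[s] - 4 * self.N).ravel(),
                      R_m[:, :, s].ravel())
        return R

    def mass_jacobian(self, m_star: np.ndarray, op: dict) -> sp.csr_matrix:
        """d(mass rows)/d(m*) as an (ns*N, ns*N) sparse matrix."""
        m_e = m_star[self.conn]
        dpdm_e = pore_fluid_pressure(m_e, self.phi0_e, self.params).dp_dm
        _, sink_dsig = self._sink_factor({"m_e": m_e})
        V, ns = self.V, self.ns
        rows, cols, vals = [], [], []
        for s in range(ns):
            i0 = s + 1
            btot = self.beta[:, :, i0].sum(axis=1)
            Kmm = V[:, None, None] * op["BKB"][:, s] * dpdm_e[:, None, :, s]
            Kmm = Kmm + np.einsum("e,ab,eb->eab", V * btot, _MASS44,
                                  dpdm_e[:, :, s])
            if s == ns - 1:
                # starvation of the element-lumped terminal sink (full block)
                Kmm = Kmm - ((V / 4.0) * self.S_ext)[:, None, None] \
                    * sink_dsig[:, None, :]
            r = np.broadcast_to((self.mdof[s] - 4 * self.N)[:, :, None],
                                Kmm.shape)
            c = np.broadcast_to((self.mdof[s] - 4 * self.N)[:, None, :],
                                Kmm.shape)
            rows.append(r.ravel()); cols.append(c.ravel()); vals.append(Kmm.ravel())
            for t in range(ns):
                if t == s:
                    continue
                bji = self.beta[:, t + 1, i0]
                Kmt = -np.einsum("e,ab,eb->eab", V * bji, _MASS44,
                                 dpdm_e[:, :, t])
                r = np.broadcast_to((self.mdof[s] - 4 * self.N)[:, :, None],
                                    Kmt.shape)
                c = np.broadcast_to((self.mdof[t] - 4 * self.N)[:, None, :],
                                    Kmt.shape)
                rows.append(r.ravel()); cols.append(c.ravel()); vals.append(Kmt.ravel())
        return sp.coo_matrix((np.concatenate(vals),
                              (np.concatenate(rows), np.concatenate(cols))),
                             shape=(ns * self.N, ns * self.N)).tocsr()

    # -- Jacobian -----------------------------------------------------------
    def jacobian(self, state: SolutionState) -> sp.csr_matrix:
        st = self._element_state(state)
        _, dpdm_e, gz, pore_q = self._pore_quantities(st)
        _, sink_dsig = self._sink_factor(st)
        V, B = self.V, self.B
        E, ns, nc = self.E, self.ns, self.nc
        J, F, Fi, FiT, Ci, trC = (st["J"], st["F"], st["Fi"], st["FiT"],
                                  st["Ci"], st["trC"])
        J23 = J ** (-2.0 / 3.0)
        gp = st["gp"]
        G = self.params.G

        K00 = np.einsum("e,eMk,eskl,eNl->esMN", J, Fi, self.K0, Fi)
        w = gp[:, None, :] + gz                                       # (E,ns,3)

        rows, cols, vals = [], [], []

        def scatter(r, c, v):
            rows.append(r.ravel())
            cols.append(np.broadcast_to(c, r.shape).ravel() if c.shape != r.shape else c.ravel())
            vals.append(v.ravel())

        # ---- K_uu: dP/dF -------------------------------------------------
        # every tangent term is an outer product of two (E,4,3) arrays, so
        # the 4th-order tensor is never formed
        Fb = F - (trC / 3.0)[:, None, None] * FiT
        FbB = np.einsum("emN,eaN->eam", Fb, B)            # (Fb B_a)_m
        FiTB = np.einsum("emN,eaN->eam", FiT, B)          # (F^{-T} B_a)_m
        FB_ = np.einsum("emN,eaN->eam", F, B)             # (F B_a)_m
        BB = np.einsum("eaN,ebN->eab", B, B)
        pJ = st["pbar"] * J
        c_iso = G * J23
        Kuu = (V * (-2.0 / 3.0) * c_iso)[:, None, None, None, None] \
            * np.einsum("eam,ebk->eambk", FbB, FiTB)
        Kuu += (V * c_iso)[:, None, None, None, None] * (
            np.einsum("eab,mk->eambk", BB, _EYE)
            - (2.0 / 3.0) * np.einsum("eam,ebk->eambk", FiTB, FB_))
        Kuu += (V * (c_iso * trC / 3.0 + pJ))[:, None, None, None, None] \
            * np.einsum("eak,ebm->eambk", FiTB, FiTB)
        Kuu -= (V * pJ)[:, None, None, None, None] \
            * np.einsum("eam,ebk->eambk", FiTB, FiTB)
        r = np.broadcast_to(self.udof[:, :, :, None, None], Kuu.shape)
        c = np.broadcast_to(self.udof[:, None, None, :, :], Kuu.shape)
        scatter(r, c, Kuu)

        # ---- K_up --------------------------------------------------------
        Kup = np.einsum("e,emN,eaN->eam", -(V * J) / 4.0, FiT, B)
        Kup4 = np.broadcast_to(Kup[:, :, :, None], (E, 4, 3, 4))
        r = np.broadcast_to(self.udof[:, :, :, None], Kup4.shape)
        c = np.broadcast_to(self.pdof[:, None, None, :], Kup4.shape)
        scatter(r, c, Kup4)

        # ---- K_pu --------------------------------------------------------
        FB = np.einsum("ekL,ebL->ebk", FiT, B)          # (E,4,3)
        vol_pu = np.einsum("e,ebk->ebk", V * J / 4.0, FB)
        Kpu = np.broadcast_to(vol_pu[:, None, :, :], (E, 4, 4, 3)).copy()
        BCg = np.einsum("eaM,eMN,eN->ea", B, Ci, gp)    # (E,4)
        BCB = np.einsum("eaM,eMN,ebN->eab", B, Ci, B)   # (E,4,4)
        Fg = np.einsum("ekN,eN->ek", FiT, gp)           # (E,3)
        coef = self.cstab * V * J
        stab = (np.einsum("ea,ebk->eabk", BCg, FB)
                - np.einsum("eab,ek->eabk", BCB, Fg)
                - np.einsum("eak,eb->eabk", FB, BCg))
        Kpu += coef[:, None, None, None] * stab
        r = np.broadcast_to(self.pdof[:, :, None, None], Kpu.shape)
        c = np.broadcast_to(self.udof[:, None, :, :], Kpu.shape)
        scatter(r, c, Kpu)

        # ---- K_pp --------------------------------------------------------
        Kpp = coef[:, None, None] * BCB
        r = np.broadcast_to(self.pdof[:, :, None], Kpp.shape)
        c = np.broadcast_to(self.pdof[:, None, :], Kpp.shape)
        scatter(r, c, Kpp)

        # ---- K_pm (same for every solved compartment) --------------------
        Kpm = -np.einsum("e,ab->eab", V, _MASS44)
        for s in range(ns):
            r = np.broadcast_to(self.pdof[:, :, None], Kpm.shape)
            c = np.broadcast_to(self.mdof[s][:, None, :], Kpm.shape)
            scatter(r, c, Kpm)

        # ---- mass-balance blocks -----------------------------------------
        BKB = np.einsum("eaM,esMN,ebN->esab", B, K00, B, optimize=True)  # (E,ns,4,4)
        NqNq = _MASS44  # (4,4) fraction of V
        for s in range(ns):
            i0 = s + 1
            # wrt p: stiffness + source anchor to compartment 1
            Kmp = V[:, None, None] * BKB[:, s] \
                + np.einsum("e,ab->eab", V * self.beta[:, 0, i0], NqNq)
            r = np.broadcast_to(self.mdof[s][:, :, None], Kmp.shape)
            c = np.broadcast_to(self.pdof[:, None, :], Kmp.shape)
            scatter(r, c, Kmp)

            # wrt u: geometric variation of K00
            t1 = np.einsum("ea,ebk->eabk", np.einsum("eaM,esM->esa", B,
                 np.einsum("esMN,esN->esM", K00, w))[:, s], FB)
            FiB = np.einsum("eMk,eaM->eak", Fi, B)        # (Fi^T B_a)[k]
            t2 = np.einsum("eak,eb->eabk", FiB,
                           np.einsum("ebM,esM->esb", B,
                                     np.einsum("esMN,esN->esM", K00, w))[:, s])
            Fw = np.einsum("ekN,esN->esk", FiT, w)[:, s]  # (E,3)
            t3 = np.einsum("eab,ek->eabk", BKB[:, s], Fw)
            Kmu = V[:, None, None, None] * (t1 - t2 - t3)
            r = np.broadcast_to(self.mdof[s][:, :, None, None], Kmu.shape)
            c = np.broadcast_to(self.udof[:, None, :, :], Kmu.shape)
            scatter(r, c, Kmu)

            # wrt m_s (same compartment): the nodal value m_b enters only
            # through z_b = z(m_b), so every term carries dpdm at node b
            btot = self.beta[:, :, i0].sum(axis=1)        # sum_k beta_{k,i}
            Kmm = V[:, None, None] * BKB[:, s] * dpdm_e[:, None, :, s]
            Kmm = Kmm + np.einsum("e,ab,eb->eab", V * btot, NqNq,
                                  dpdm_e[:, :, s])
            if s == ns - 1:
                # starvation of the element-lumped terminal sink (full block)
                Kmm = Kmm - ((V / 4.0) * self.S_ext)[:, None, None] \
                    * sink_dsig[:, None, :]
            r = np.broadcast_to(self.mdof[s][:, :, None], Kmm.shape)
            c = np.broadcast_to(self.mdof[s][:, None, :], Kmm.shape)
            scatter(r, c, Kmm)

            # wrt m_t, t != s (other solved compartments)
            for t in range(ns):
                if t == s:
                    continue
                bji = self.beta[:, t + 1, i0]
                Kmt = -np.einsum("e,ab,eb->eab", V * bji, NqNq,
                                 dpdm_e[:, :, t])
                r = np.broadcast_to(self.mdof[s][:, :, None], Kmt.shape)
                c = np.broadcast_to(self.mdof[t][:, None, :], Kmt.shape)
                scatter(r, c, Kmt)

        Jmat = sp.coo_matrix((np.concatenate(vals),
                              (np.concatenate(rows), np.concatenate(cols))),
                             shape=(self.ndof, self.ndof)).tocsr()
        return Jmat

    # -- boundary conditions -------------------------------------------------
    def pinned_dofs(self) -> np.ndarray:
        """Dirichlet dofs: six displacement components pinning the rigid
        modes (3-2-1 scheme) plus the inactive pore-volume dofs."""
        X = self.mesh.nodes
        lo, hi = X.min(axis=0), X.max(axis=0)
        n1 = int(np.argmin(np.linalg.norm(X - lo, axis=1)))
        n2 = int(np.argmin(np.linalg.norm(X - [hi[0], lo[1], lo[2]], axis=1)))
        n3 = int(np.argmin(np.linalg.norm(X - [lo[0], hi[1], lo[2]], axis=1)))
        pins = np.array([3 * n1, 3 * n1 + 1, 3 * n1 + 2,
                         3 * n2 + 1, 3 * n2 + 2, 3 * n3 + 2])
        return np.concatenate([pins, self.inactive_mdofs])

    def apply_bcs(self, R: np.ndarray, Jmat: sp.csr_matrix, x: np.ndarray):
        fixed = self.pinned_dofs()
        R = R.copy()
        R[fixed] = x[fixed]
        Jmat = Jmat.tolil()
        for d in fixed:
            Jmat.rows[d] = [int(d)]
            Jmat.data[d] = [1.0]
        return R, Jmat.tocsr()

    # -- norms ---------------------------------------------------------------
    def block_norms(self, R: np.ndarray) -> np.ndarray:
        N = self.N
        blocks = [R[: 3 * N], R[3 * N: 4 * N]]
        blocks += [R[(4 + s) * N: (5 + s) * N] for s in range(self.ns)]
        return np.array([np.linalg.norm(b) for b in blocks])

    def block_scales(self) -> np.ndarray:
        """Natural magnitude of each residual block, built without
        cancellation from the problem data: a unit of uncorrelated stress
        disequilibrium at the driving pressure scale for momentum, a
        reference volume mismatch for incompressibility, and the
        no-cancellation source magnitude for each mass balance."""
        p_ref = max(float(np.max(np.abs(self.p1bar))), 1.0)
        VB = self.V[:, None, None] * self.B               # (E,4,3)
        s_u = p_ref * float(np.sqrt(np.sum(VB**2)))
        m_ref = 0.01
        s_p = m_ref * float(np.sqrt(np.sum((self.V / 4.0) ** 2 * 4.0)))
        scales = [s_u, s_p]
        for s in range(self.ns):
            i0 = s + 1                                   # 0-based compartment
            src = np.abs(self.S_ext) if i0 == self.nc - 1 else np.zeros(self.E)
            src = src + self.beta[:, :, i0].sum(axis=1) * p_ref
            s_m = float(np.sqrt(np.sum((self.V * src / 4.0) ** 2 * 4.0)))
            scales.append(max(s_m, 1e-30))
        return np.array(scales)


def assemble_system(mesh: TetMesh, fields: PorousFields, state: SolutionState,
                    params: MaterialParams, config: SolverConfig | None = None):
    """Residual vector and exact Jacobian of the discrete steady problem."""
    sys_ = PoroelasticSystem(mesh, fields, params, config)
    return sys_.residual(state), sys_.jacobian(state)


def newton_solve(mesh: TetMesh, fields: PorousFields, params: MaterialParams,
                 config: SolverConfig | None = None,
                 state0: SolutionState | None = None):
    """Solve the steady coupled problem; returns (state, info dict).

    Strategy: a direct damped Newton attempt first; if the problem is too
    stiff (starved sink pockets, deep tube-law branches), fall back to
    pseudo-transient continuation - implicit-Euler pseudo-time steps on the
    added-pore-volume equations, each solved by an inner damped Newton, with
    the pseudo-timestep adapted until the steady equations take over.  The
    pore-volume unknowns are iterated in log-porosity variables
    m* = phi0 (e^w - 1), which makes positivity of the current porosity
    structural and linearizes the logarithmic branch of the tube law.
    """
    config = config or SolverConfig()
    return _ImplicitSolver(mesh, fields, params, config).solve(state0)


class _ImplicitSolver:
    """Damped Newton / pseudo-transient driver in pore-pressure variables.

    The nodal unknown for each solved compartment is z = p_PV + p_c, the
    m*-dependent part of the pore pressure; m*(z) is recovered by inverting
    the strictly monotone tube law per node.  In z the exchange sources are
    nearly linear and the chain rule dm/dz = 1/p'(m) exactly equilibrates
    the exponential/logarithmic stiffness of the tube law, which plain
    Newton on m* (or on log-porosity) badly overshoots.
    """

    def __init__(self, mesh, fields, params, config):
        self.sys = PoroelasticSystem(mesh, fields, params, config)
        self.mesh, self.fields, self.params, self.config = (mesh, fields,
                                                            params, config)
        sys_ = self.sys
        self.N, self.ns = sys_.N, sys_.ns
        self.phi0n = sys_.phi0_node
        self.fixed = sys_.pinned_dofs()
        self.sca = sys_.block_scales()
        self.rep = np.repeat(self.sca, [3 * self.N, self.N] + [self.N] * self.ns)
        Vn = np.zeros(self.N)
        np.add.at(Vn, sys_.conn.ravel(), np.repeat(sys_.V / 4.0, 4))
        self.Vn = Vn
        # pressure box.  Upward: a generous multiple of the driving pressure
        # (the exponential branch gives v ~ ln(z/q1)/q3 ~ 0.09 there).
        # Downward: the logarithmic branch makes pressure depth brutal in
        # porosity - z = q2 ln(v/phi0) - and sinks starve (shut down) around
        # v/phi0 ~ 1e-2, so no equilibrium ever needs v/phi0 < 1e-3; bounding
        # there keeps dp/dm and the z-columns of the Jacobian well scaled.
        p_ref = max(float(np.max(np.abs(fields.p1bar))), 1.0)
        self.z_hi = 1.5 * p_ref + 1e3
        self.z_lo = float(params.q2 * np.log(1e-3))

    # -- tube-law inversion --------------------------------------------------
    def _m_of_z(self, z, v_init=None):
        """Invert p_PV(m) + p_c(m) = z per node (vectorized, monotone)."""
        phi0 = self.phi0n
        v = v_init.copy() if v_init is not None else phi0.copy()
        for _ in range(80):
            pp = pore_fluid_pressure(v - phi0, phi0, self.params)
            f = pp.total - z
            # Newton in ln v keeps v positive; dp/d(ln v) = dp/dm * v
            step = np.clip(f / (pp.dp_dm * v), -1.0, 1.0)
            v = v * np.exp(-step)
            if np.max(np.abs(f)) <= 1e-12 * max(1.0, np.max(np.abs(z))):
                break
        return v - phi0, v

    def _z_of_m(self, m):
        return pore_fluid_pressure(m, self.phi0n, self.params).total

    # -- helpers ------------------------------------------------------------
    def _bc(self, R, x):
        R = R.copy()
        R[self.fixed] = x[self.fixed]
        return R

    def _merit(self, Rv):
        with np.errstate(over="ignore"):
            return float(np.linalg.norm(Rv / self.rep))

    def _relmax(self, Rv):
        return float(np.max(self.sys.block_norms(Rv) / self.sca))

    def _sub_newton(self, z, v, rows_cols, max_it, tol_rel):
        """Damped Newton on the elasticity rows or the full system.

        ``rows_cols`` is "elastic" (u,p unknowns, m* frozen) or "full"
        (all unknowns, z-scaled).  Returns
        (z, v, n_its, relmax of the selected residual rows).
        """
        N, ns = self.N, self.ns
        cfg = self.config
        sel_e = np.arange(4 * N)
        sel = {"elastic": sel_e, "full": np.arange(self.sys.ndof)}[rows_cols]
        state = SolutionState(u=self._u.copy(), p=self._p.copy(),
                              m_star=v - self.phi0n)
        x = state.pack()
        R = self.sys.residual(state)
        Rb = self._bc(R, x)
        cur = float(np.linalg.norm(Rb[sel] / self.rep[sel]))
        n_done = 0
        for _ in range(max_it):
            if cur <= tol_rel:
                break
            Jmat = self.sys.jacobian(state)
            _, Jb = self.sys.apply_bcs(R, Jmat, x)
            if rows_cols == "elastic":
                A = Jb[sel_e][:, sel_e]
                b = -Rb[sel_e]
            else:
                dpdm = pore_fluid_pressure(state.m_star, self.phi0n,
                                           self.params).dp_dm
                scale = np.ones(self.sys.ndof)
                scale[4 * N:] = (1.0 / dpdm).T.ravel()
                A = Jb @ sp.diags(scale)
                b = -Rb
            with np.errstate(all="ignore"):
                d = spla.spsolve(A.tocsc(), b)
            if not np.all(np.isfinite(d)):
                break
            lam, ok = 1.0, False
            for _bt in range(cfg.backtrack_max + 3):
                z_c, v_c = z, v
                if rows_cols == "full":
                    dz = d[4 * N:].reshape(ns, N).T
                    z_c = np.clip(z + lam * dz, self.z_lo, self.z_hi)
                    m_c, v_c = self._m_of_z(z_c, v_init=v)
                else:
                    m_c = state.m_star
                du = d if rows_cols == "elastic" else d[:4 * N]
                u_c = state.u + lam * du[:3 * N].reshape(N, 3)
                p_c = state.p + lam * du[3 * N:4 * N]
                st_c = SolutionState(u=u_c.copy(), p=p_c.copy(),
                                     m_star=m_c.copy())
                x_c = st_c.pack()
                try:
                    R_c = self.sys.residual(st_c)
                except (FloatingPointError, ValueError):
                    lam *= 0.5
                    continue
                Rb_c = self._bc(R_c, x_c)
                cur_c = float(np.linalg.norm(Rb_c[sel] / self.rep[sel]))
                if np.isfinite(cur_c) and cur_c < cur:
                    ok = True
                    break
                lam *= 0.5
            if not ok:
                break
            z, v, state, x, R, Rb, cur = z_c, v_c, st_c, x_c, R_c, Rb_c, cur_c
            self._u, self._p = state.u.copy(), state.p.copy()
            n_done += 1
        return z, v, n_done, cur

    def _active_mask(self, z, R_m):
        """KKT-active dofs of the porosity-floor variational inequality.

        The steady mass balance is solved subject to the pressure box
        (equivalently a porosity floor): dofs pinned at a bound whose
        residual points further out satisfy the first-order optimality
        conditions there, so their residual is excluded from convergence
        norms and reported as the flow deficit (sink demand the local
        transport capacity cannot supply).
        """
        tol_z = 1e-9 * (self.z_hi - self.z_lo)
        at_lo = (z <= self.z_lo + tol_z).T.ravel()
        at_hi = (z >= self.z_hi - tol_z).T.ravel()
        return (at_lo & (R_m > 0)) | (at_hi & (R_m < 0))

    def _solve_mass(self, z, v, max_it: int = 120):
        """Active-set Newton in z on the mass rows at frozen (u, p).

        Uses the cached geometric operator (the expensive kinematic pieces
        do not change while u and p are frozen), with implicit-Euler
        pseudo-time damping as the fallback when plain Newton stalls.
        Returns (z, v, n_its, masked relmax of the mass rows).
        """
        N, ns = self.N, self.ns
        cfg = self.config
        state = SolutionState(u=self._u.copy(), p=self._p.copy(),
                              m_star=v - self.phi0n)
        op = self.sys.mass_operator(state)
        rep_m = self.rep[4 * N:]
        fixed_rel = self.fixed[self.fixed >= 4 * N] - 4 * N

        def resid(m_star):
            R = self.sys.mass_residual(m_star, op)
            R[fixed_rel] = m_star.T.ravel()[fixed_rel]
            return R

        def masked(R, z_cur):
            Rm = R.copy()
            Rm[self._active_mask(z_cur, R)] = 0.0
            return Rm

        def norm(R):
            return float(np.linalg.norm(R / rep_m))

        R = resid(v - self.phi0n)
        cur = norm(masked(R, z))
        tol_abs = cfg.newton_tol
        n_done = 0
        stalled = 0
        dtau = np.inf
        m_old = (v - self.phi0n).copy()
        while n_done < max_it and cur > tol_abs and stalled < 3:
            m_star = v - self.phi0n
            dpdm = pore_fluid_pressure(m_star, self.phi0n, self.params).dp_dm
            A = self.sys.mass_jacobian(m_star, op) @ sp.diags((1.0 / dpdm).T.ravel())
            active = self._active_mask(z, R)
            pinned = np.union1d(fixed_rel, np.flatnonzero(active))
            Rd = R.copy()
            Rd[pinned] = 0.0
            if np.isfinite(dtau):
                dd = (self.Vn[:, None] / dpdm / dtau).T.ravel()
                dd[pinned] = 0.0
                A = A + sp.diags(dd)
                trans = (self.Vn[:, None] * (m_star - m_old) / dtau).T.ravel()
                trans[pinned] = 0.0
                Rd = Rd + trans
            A = A.tolil()
            for dref in pinned:
                A.rows[dref] = [int(dref)]
                A.data[dref] = [1.0]
            with np.errstate(all="ignore"):
                dz_flat = spla.spsolve(A.tocsr().tocsc(), -Rd)
            if not np.all(np.isfinite(dz_flat)):
                dtau = cfg.ptc_dtau0 if np.isinf(dtau) else dtau / 4.0
                if dtau < 1e-9:
                    break
                continue
            dz = dz_flat.reshape(ns, N).T
            lam, ok = 1.0, False
            base = norm(masked(Rd, z))
            for _bt in range(cfg.backtrack_max + 3):
                z_c = np.clip(z + lam * dz, self.z_lo, self.z_hi)
                m_c, v_c = self._m_of_z(z_c, v_init=v)
                R_c = resid(m_c)
                if np.isfinite(dtau):
                    trans_c = (self.Vn[:, None] * (m_c - m_old) / dtau).T.ravel()
                    trans_c[pinned] = 0.0
                    cur_ref = norm(masked(R_c + trans_c, z_c))
                else:
                    cur_ref = norm(masked(R_c, z_c))
                if np.isfinite(cur_ref) and cur_ref < max(base, cur):
                    ok = True
                    break
                lam *= 0.5
            n_done += 1
            if not ok:
                dtau = cfg.ptc_dtau0 if np.isinf(dtau) else dtau / 4.0
                if dtau < 1e-9:
                    break
                continue
            z, v, R = z_c, v_c, R_c
            prev = cur
            cur = norm(masked(R, z))
            stalled = stalled + 1 if cur > 0.9 * prev else 0
            if np.isfinite(dtau):
                m_old = (v - self.phi0n).copy()
                dtau *= 2.0
                if dtau > 1e3 or cur <= 1e-2:
                    dtau = np.inf
        Rm = masked(R, z)
        rel = float(np.max(self.sys.block_norms(
            np.concatenate([np.zeros(4 * N), Rm]))[2:] / self.sca[2:]))
        deficit = float(np.sum(np.abs(R[self._active_mask(z, R)])))
        return z, v, n_done, rel, deficit

    # -- driver -------------------------------------------------------------
    def solve(self, state0: SolutionState | None = None):
        """Staggered (mass / elasticity) sweeps with a monolithic polish.

        The mass subsystem is solved in pore-pressure variables z with the
        displacement and skeleton pressure frozen; the finite-strain
        elasticity pair (u, p) is then updated at frozen m*.  The coupling
        between the two is weak (the skeleton pressure is of order G times
        the volumetric strain, far below the pore-pressure scale), so a few
        sweeps reach the basin where monolithic Newton converges
        quadratically.  Stiff mass solves are damped with implicit-Euler
        pseudo-time steps.
        """
        config = self.config
        if state0 is None:
            state0 = initial_state_from_poiseuille(self.mesh, self.fields,
                                                   self.params)
        self._u, self._p = state0.u.copy(), state0.p.copy()
        z = np.clip(self._z_of_m(state0.m_star), self.z_lo, self.z_hi)
        m, v = self._m_of_z(z)
        total = 0
        hist = []

        def steady_rel():
            """Masked steady residual: KKT-active porosity-floor dofs are
            excluded and accounted as the flow deficit."""
            st = SolutionState(u=self._u.copy(), p=self._p.copy(),
                               m_star=v - self.phi0n)
            Rb = self._bc(self.sys.residual(st), st.pack())
            N = self.N
            z_cur = self._z_of_m(st.m_star)
            act = self._active_mask(z_cur, Rb[4 * N:])
            deficit = float(np.sum(np.abs(Rb[4 * N:][act])))
            Rb = Rb.copy()
            Rb[4 * N:][act] = 0.0
            return self._relmax(Rb), st, deficit, int(act.sum())

        for sweep in range(config.max_sweeps):
            # mass solve (u, p frozen) with cached geometric operator
            z, v, n_m, rel_m, _ = self._solve_mass(z, v)
            total += n_m
            # elasticity solve (m* frozen)
            z, v, n_e, rel_e = self._sub_newton(
                z, v, "elastic", config.max_newton, 0.1 * config.newton_tol)
            total += n_e
            rel, st, deficit, n_act = steady_rel()
            hist.append(rel)
            if config.verbose:
                log.info("sweep %d: mass rel=%.2e elastic rel=%.2e "
                         "steady rel=%.2e deficit=%.3g (%d active, "
                         "total %d its)", sweep, rel_m, rel_e, rel, deficit,
                         n_act, total)
            if rel <= config.newton_tol:
                return st, {"iterations": n_m + n_e, "total_iterations": total,
                            "residuals": hist, "converged": True,
                            "sweeps": sweep + 1, "flow_deficit": deficit,
                            "n_floor_dofs": n_act}
            # monolithic polish once the sweeps are close (only meaningful
            # when no porosity-floor constraint is active)
            if n_act == 0 and (rel <= 1e-4 or (sweep >= 2 and rel <= 1e-2)):
                z, v, n_f, rel_f = self._sub_newton(
                    z, v, "full", 12, 0.1 * config.newton_tol)
                total += n_f
                rel, st, deficit, n_act = steady_rel()
                hist.append(rel)
                if config.verbose:
                    log.info("  polish: %d its -> steady rel=%.2e", n_f, rel)
                if rel <= config.newton_tol:
                    return st, {"iterations": n_f,
                                "total_iterations": total,
                                "residuals": hist, "converged": True,
                                "sweeps": sweep + 1, "flow_deficit": deficit,
                                "n_floor_dofs": n_act}
        raise NewtonDivergenceError(
            f"staggered solve did not converge in {config.max_sweeps} sweeps "
            f"(steady rel {hist[-1]:.3e}, {total} Newton iterations)")


# ---------------------------------------------------------------------------
# manufactured-solution verification of the Darcy sub-solver
# ---------------------------------------------------------------------------

@dataclass
class ManufacturedDarcy:
    """Manufactured solution p(x) with source f = -div(K grad p)."""

    p_exact: callable
    f: callable
    K: np.ndarray = field(default_factory=lambda: np.eye(3))

    @classmethod
    def sincos(cls, K=None) -> "ManufacturedDarcy":
        """p = sin(pi x) cos(pi y) on the unit cube."""
        K = np.eye(3) if K is None else np.asarray(K, dtype=float)
        kx, ky = K[0, 0], K[1, 1]

        def p(x):
            return np.sin(np.pi * x[..., 0]) * np.cos(np.pi * x[..., 1])

        def f(x):
            return (kx + ky) * np.pi**2 * p(x)

        return cls(p_exact=p, f=f, K=K)


def solve_darcy_p1(mesh: TetMesh, mms: ManufacturedDarcy) -> np.ndarray:
    """P1 Galerkin solve of -div(K grad p) = f with exact Dirichlet BCs."""
    B, V, conn = mesh.grads, mesh.volumes, mesh.tets
    Kel = np.broadcast_to(mms.K, (mesh.n_elements, 3, 3))
    Ke = np.einsum("e,eaM,eMN,ebN->eab", V, B, Kel, B)
    rows = np.broadcast_to(conn[:, :, None], Ke.shape).ravel()
    cols = np.broadcast_to(conn[:, None, :], Ke.shape).ravel()
    A = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    xq = mesh.quad_points()
    fq = mms.f(xq)
    b = np.zeros(mesh.n_nodes)
    Fe = np.einsum("e,qa,eq->ea", V / 4.0, QUAD_BARY, fq)
    np.add.at(b, conn.ravel(), Fe.ravel())

    bnd = mesh.boundary_nodes
    pb = np.zeros(mesh.n_nodes)
    pb[bnd] = mms.p_exact(mesh.nodes[bnd])
    free = np.setdiff1d(np.arange(mesh.n_nodes), bnd)
    rhs = b[free] - A[free][:, bnd] @ pb[bnd]
    p = pb.copy()
    p[free] = spla.spsolve(A[free][:, free].tocsc(), rhs)
    return p


def _l2_error(mesh: TetMesh, p_h: np.ndarray, p_exact) -> float:
    xq = mesh.quad_points()
    ph_q = np.einsum("qa,ea->eq", QUAD_BARY, p_h[mesh.tets])
    diff = ph_q - p_exact(xq)
    return float(np.sqrt(np.einsum("e,eq->", mesh.volumes / 4.0, diff**2)))


def darcy_mms_check(mesh_sequence, mms: ManufacturedDarcy | None = None):
    """Observed L2 convergence order of the P1 Darcy solve.

    ``mesh_sequence``: >= 3 meshes, each halving h.  Returns (order, errors)
    with order the mean of successive log2 error ratios.
    """
    meshes = list(mesh_sequence)
    if len(meshes) < 3:
        raise ValueError("need at least 3 meshes for an observed order")
    mms = mms or ManufacturedDarcy.sincos()
    errs = []
    for m in meshes:
        p = solve_darcy_p1(m, mms)
        errs.append(_l2_error(m, p, mms.p_exact))
    orders = [np.log2(errs[i] / errs[i + 1]) for i in range(len(errs) - 1)]
    return float(np.mean(orders)), errs
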