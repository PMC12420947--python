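"""Pointwise material laws for the poroelastic mixture.

The skeleton is an incompressible isochoric neo-Hookean solid, each fluid
compartment carries a tube-law pore-volume energy (vessels inflate with pore
pressure) plus an arctangent barrier that keeps the current porosity
``v = m* + phi0`` above a critical floor.  The free energy is

    Psi(C, p, m*) = W(C_bar) + sum_i [U_PV_i(m*_i) + U_c_i(m*_i)]
                    - p (J - 1 - sum_i m*_i)

with W = G/2 (I1_bar - 3).  All pressure-like outputs are exact derivatives
of these energies; tests enforce that with central finite differences.

Units: mm-Pa-s internally.  ``MaterialParams`` takes the moduli G, q1, q2 in
kPa (the unit the tube-law constants are conventionally quoted in) and
converts on construction; everything downstream sees Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import KPA_TO_PA

__all__ = [
    "MaterialParams",
    "Kinematics",
    "PorePressureParts",
    "kinematics_from_grad",
    "tube_law_energy",
    "penalization_energy",
    "pore_fluid_pressure",
    "strain_energy_W",
    "pk2_stress",
    "pull_back_permeability",
]

# exponent clip: e^x with x>~700 overflows; the barrier makes such states
# unreachable in converged solutions, but Newton trial states may visit them
_EXP_CLIP = 60.0


@dataclass
class MaterialParams:
    """Material constants of the poroelastic medium.

    Parameters
    ----------
    G_kpa : skeleton shear modulus, kPa (default 5; not fixed by the tube law).
    q1_kpa, q2_kpa, q3 : tube-law constants (0.022 kPa, 1.009 kPa, 80).
    c : penalization reference pressure, Pa.
    eps : penalization width (dimensionless porosity units).
    phi_crit : critical porosity below which compression is penalized.
    mu : blood viscosity, Pa s.
    alpha : pressure-stabilization parameter of the P1-P1 discretization.
    phi_floor : floor applied to reference porosities fed to the tube law,
        so elements without vessels in a compartment still have a valid
        (very stiff) pore-pressure law.
    """

    G_kpa: float = 5.0
    q1_kpa: float = 0.022
    q2_kpa: float = 1.009
    q3: float = 80.0
    # The barrier scale c must keep the pore-pressure law monotone in m*:
    # the arctan bump contributes a negative slope of up to ~0.65 c/eps^2,
    # which must stay below the tube-law slope q2/v for the porosity range
    # of interest; with eps = 1e-3 that requires c below ~2.5 Pa.
    c: float = 1.0
    eps: float = 0.001
    phi_crit: float = 1.0e-5
    mu: float = 0.004
    alpha: float = 0.2
    phi_floor: float = 1.0e-4

    # Pa-valued fields, filled in __post_init__
    G: float = field(init=False)
    q1: float = field(init=False)
    q2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.G_kpa <= 0:
            raise ValueError("shear modulus G must be positive")
        if self.q3 <= 0:
            raise ValueError("tube-law exponent q3 must be positive")
        if not (0.0 < self.eps < 1.0):
            raise ValueError("eps must lie in (0, 1)")
        if self.phi_crit < 0:
            raise ValueError("phi_crit must be non-negative")
        if self.mu <= 0:
            raise ValueError("viscosity mu must be positive")
        self.G = self.G_kpa * KPA_TO_PA
        self.q1 = self.q1_kpa * KPA_TO_PA
        self.q2 = self.q2_kpa * KPA_TO_PA


@dataclass
class Kinematics:
    """Deformation measures at a point: F, J=det F, C, C_bar, I1_bar."""

    F: np.ndarray
    J: float
    C: np.ndarray
    C_bar: np.ndarray
    I1_bar: float


def kinematics_from_grad(grad_u: np.ndarray) -> Kinematics:
    """Build kinematic quantities from the displacement gradient (3x3)."""
    grad_u = np.asarray(grad_u, dtype=float)
    if grad_u.shape != (3, 3):
        raise ValueError("grad_u must be a 3x3 tensor")
    F = np.eye(3) + grad_u
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise ValueError(f"non-positive Jacobian determinant J={J}")
    C = F.T @ F
    C_bar = J ** (-2.0 / 3.0) * C
    return Kinematics(F=F, J=J, C=C, C_bar=C_bar, I1_bar=float(np.trace(C_bar)))


# ---------------------------------------------------------------------------
# pore-fluid energies and pressures
# ---------------------------------------------------------------------------

def tube_law_energy(m_star, phi0, params: MaterialParams):
    """Tube-law pore-volume energy U_PV(m*), shifted so U_PV(0) = 0.

    U_PV = (q1/q3)(e^{q3 v} - e^{q3 phi0}) - q1 e^{q3 phi0} m*
           + q2 (v ln(v/phi0) - m*),          v = m* + phi0
    """
    q1, q2, q3 = params.q1, params.q2, params.q3
    v = np.asarray(m_star, dtype=float) + phi0
    if np.any(v <= 0):
        raise ValueError("current porosity m* + phi0 must be positive")
    e_v = np.exp(np.clip(q3 * v, None, _EXP_CLIP))
    e_0 = np.exp(np.clip(q3 * phi0, None, _EXP_CLIP))
    m = v - phi0
    return (q1 / q3) * (e_v - e_0) - q1 * e_0 * m + q2 * (v * np.log(v / phi0) - m)


def penalization_energy(m_star, phi0, params: MaterialParams):
    """Porosity barrier U_c = c atan((v - phi_crit)/eps)."""
    v = np.asarray(m_star, dtype=float) + phi0
    return params.c * np.arctan((v - params.phi_crit) / params.eps)


@dataclass
class PorePressureParts:
    """Pore-pressure decomposition at given added pore volume m*.

    p_pore = p + p_PV + p_c; this object carries the m*-dependent parts and
    their first and second derivatives with respect to m*.
    """

    p_PV: np.ndarray
    p_c: np.ndarray
    dp_dm: np.ndarray
    d2p_dm2: np.ndarray

    @property
    def total(self) -> np.ndarray:
        """p_PV + p_c (add the skeleton pressure p for the full pore pressure)."""
        return self.p_PV + self.p_c


def pore_fluid_pressure(m_star, phi0, params: MaterialParams) -> PorePressureParts:
    """Pore pressure contributions p_PV, p_c and d(p_PV+p_c)/dm*.

    p_PV = dU_PV/dm* = q1 (e^{q3 v} - e^{q3 phi0}) + q2 ln(v / phi0)
    p_c  = dU_c/dm*  = c eps / (eps^2 + (v - phi_crit)^2)

    p_PV(m*=0) = 0 exactly; p_PV is strictly increasing in m*.
    Accepts scalars or arrays (broadcast over m_star and phi0).
    """
    q1, q2, q3 = params.q1, params.q2, params.q3
    c, eps, phic = params.c, params.eps, params.phi_crit
    m_star = np.asarray(m_star, dtype=float)
    phi0 = np.asarray(phi0, dtype=float)
    v = m_star + phi0
    if np.any(v <= 0):
        raise ValueError("current porosity m* + phi0 must be positive")
    e_v = np.exp(np.clip(q3 * v, None, _EXP_CLIP))
    e_0 = np.exp(np.clip(q3 * phi0, None, _EXP_CLIP))
    p_pv = q1 * (e_v - e_0) + q2 * np.log(v / phi0)
    d = v - phic
    den = eps * eps + d * d
    p_c = c * eps / den
    dp_dm = q1 * q3 * e_v + q2 / v - 2.0 * c * eps * d / den**2
    d2p = q1 * q3 * q3 * e_v - q2 / v**2 + c * eps * (6.0 * d * d - 2.0 * eps * eps) / den**3
    return PorePressureParts(p_PV=p_pv, p_c=p_c, dp_dm=dp_dm, d2p_dm2=d2p)


# ---------------------------------------------------------------------------
# stress and permeability pull-back
# ---------------------------------------------------------------------------

def strain_energy_W(C: np.ndarray, G_pa: float) -> float:
    """Isochoric neo-Hookean energy W(C) = G/2 (I1_bar - 3) as a function of C."""
    C = np.asarray(C, dtype=float)
    detC = np.linalg.det(C)
    if detC <= 0:
        raise ValueError("C must be positive definite")
    I1_bar = detC ** (-1.0 / 3.0) * np.trace(C)
    return 0.5 * G_pa * (I1_bar - 3.0)


def pk2_stress(kin: Kinematics, p: float, G_pa: float) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dPsi/dC.

    S = G J^{-2/3} (I - (tr C / 3) C^{-1} J^{-2/3} ... ) written as
    S = G J^{-2/3} (I - (I1_bar/3) J^{2/3} C^{-1} / ... ); concretely:
    S = G J^{-2/3} (I - (tr C / 3) C^{-1}) - p J C^{-1}.
    """
    Cinv = np.linalg.inv(kin.C)
    J23 = kin.J ** (-2.0 / 3.0)
    trC = float(np.trace(kin.C))
    S = G_pa * J23 * (np.eye(3) - (trC / 3.0) * Cinv) - p * kin.J * Cinv
    return 0.5 * (S + S.T)


def pull_back_permeability(K0: np.ndarray, kin: Kinematics, dp_dm: float):
    """Lagrangian permeability K00 = J F^{-1} K0 F^{-T} and K0m = K00 dp/dm*."""
    K0 = np.asarray(K0, dtype=float)
    Finv = np.linalg.inv(kin.F)
    K00 = kin.J * Finv @ K0 @ Finv.T
    K00 = 0.5 * (K00 + K00.T)
    return K00, K00 * dp_dm
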