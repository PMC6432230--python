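"""Potentials, forces and the analytic bulk chemical quantities.

Interactions
------------
bond      ``Ub(r)    = -eps0 + ks (r - d)^2 / 2``   between adjacent
          filament monomers; the grafted seed bond (ranks 1-2) is rigid
          and contributes no energy.
bend      ``Ubend(t) = kappa (1 - cos t)``          for every triple of
          adjacent monomers, including the seed pair, which anchors the
          filament orientation normal to the grafting wall.
wall      purely repulsive 9-3 potential
          ``Uw(s) = eps_w {(3 sqrt3 / 2)[(d/s)^9 - (d/s)^3] + 1}``
          truncated at its minimum ``s_c = 3^(1/6) d``; ``s`` is the
          distance from the wall plane (both the fixed grafting wall at
          x = 0 and the mobile wall at x = L).

Free monomers are ideal: they interact with the walls only.  A filament
of ``j`` monomers carries ``j - 2`` bond terms and ``j - 2`` bend terms.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import SimulationParams

__all__ = [
    "bond_energy", "bend_energy", "wall_energy", "wall_force_mag",
    "bulk_equilibrium_constant", "compute_forces", "EnergyBreakdown",
]

_W93 = 3.0 * math.sqrt(3.0) / 2.0  # prefactor of the 9-3 wall potential


# ---------------------------------------------------------------------------
# scalar potentials (njit so the dynamics kernel can inline them)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _bond_energy(r, d, ks, eps0):
    return -eps0 + 0.5 * ks * (r - d) * (r - d)


@njit(cache=True, inline="always")
def _bend_energy(cos_theta, kappa):
    return kappa * (1.0 - cos_theta)


@njit(cache=True, inline="always")
def _wall_energy(s, d, eps_w, s_c):
    if s > s_c:
        return 0.0
    y = (d / s) ** 3
    return eps_w * (_W93 * (y * y * y - y) + 1.0)


@njit(cache=True, inline="always")
def _wall_force_mag(s, d, eps_w, s_c):
    """Magnitude of the repulsive force -dUw/ds (>= 0), pushing away from the wall."""
    if s > s_c:
        return 0.0
    y3 = (d / s) ** 3
    return eps_w * _W93 * (9.0 * y3 * y3 * y3 - 3.0 * y3) / s


def bond_energy(r, params: SimulationParams | None = None):
    """Stretching energy of one filament bond at length ``r`` [kBT]."""
    p = params or SimulationParams()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    return -p.eps0 + 0.5 * p.ks * (r - p.d) ** 2


def bend_energy(theta, params: SimulationParams | None = None):
    """Bending energy at angle ``theta`` between adjacent bonds [kBT].

    ``theta = 0`` is the straight continuation.
    """
    p = params or SimulationParams()
    return p.kappa_bend * (1.0 - np.cos(np.asarray(theta, dtype=float)))


def wall_energy(s, params: SimulationParams | None = None):
    """Repulsive 9-3 monomer-wall energy at distance ``s`` from the wall [kBT]."""
    p = params or SimulationParams()
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError(
            "monomer-wall distance <= 0: a particle crossed a wall "
            "(time step too large?)")
    y = (p.d / s) ** 3
    out = p.eps_w * (_W93 * (y ** 3 - y) + 1.0)
    return np.where(s > p.s_c, 0.0, out)


def wall_force_mag(s, params: SimulationParams | None = None):
    """Repulsive force magnitude -dUw/ds at distance ``s`` [kBT/d]."""
    p = params or SimulationParams()
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("monomer-wall distance must be positive")
    y3 = (p.d / s) ** 3
    out = p.eps_w * _W93 * (9.0 * y3 ** 3 - 3.0 * y3) / s
    return np.where(s > p.s_c, 0.0, out)


# ---------------------------------------------------------------------------
# analytic chemistry
# ---------------------------------------------------------------------------

def bulk_equilibrium_constant(params: SimulationParams | None = None):
    """Bulk (de)polymerization equilibrium constant and critical state.

    Returns ``(K0, rho1c, mu1c_star)`` where

    ``K0 = e^(beta eps0) (2 pi d^4 / Lp) sqrt(2 pi / (beta ks d^2))
           [1 - e^(-2 Lp / d)]``   [d^3],

    ``rho1c = 1 / K0`` is the critical free-monomer density and
    ``mu1c* = kBT ln(rho1c d^3)`` the critical effective chemical
    potential.  With the default parameters K0 = 39.07 d^3.
    """
    p = params or SimulationParams()
    Lp = p.Lp
    K0 = (math.exp(p.beta * p.eps0)
          * (2.0 * math.pi * p.d ** 4 / Lp)
          * math.sqrt(2.0 * math.pi / (p.beta * p.ks * p.d ** 2))
          * (1.0 - math.exp(-2.0 * Lp / p.d)))
    rho1c = 1.0 / K0
    mu1c_star = p.kBT * math.log(rho1c * p.d ** 3)
    return K0, rho1c, mu1c_star


def tip_bond_weight(params: SimulationParams | None = None):
    """Configurational weight of one tip bond, ``Z_el = K0 e^(-beta eps0)`` [d^3].

    The integral of ``exp[-beta(spring + bend)]`` over the position of a
    tip monomer relative to its filament, which normalizes the reactive
    capture volume.
    """
    p = params or SimulationParams()
    return bulk_equilibrium_constant(p)[0] * math.exp(-p.beta * p.eps0)


# ---------------------------------------------------------------------------
# full-state forces (NumPy reference; the production path lives in _kernels)
# ---------------------------------------------------------------------------

class EnergyBreakdown:
    """Per-component energies [kBT] and longitudinal wall forces [kBT/d]."""

    __slots__ = ("U_bond", "U_bend", "U_wall_fixed", "U_wall_mobile",
                 "F_w_bun", "F_w_m")

    def __init__(self, U_bond=0.0, U_bend=0.0, U_wall_fixed=0.0,
                 U_wall_mobile=0.0, F_w_bun=0.0, F_w_m=0.0):
        self.U_bond = U_bond
        self.U_bend = U_bend
        self.U_wall_fixed = U_wall_fixed
        self.U_wall_mobile = U_wall_mobile
        self.F_w_bun = F_w_bun
        self.F_w_m = F_w_m

    @property
    def total_potential(self):
        return self.U_bond + self.U_bend + self.U_wall_fixed + self.U_wall_mobile

    def __repr__(self):  # pragma: no cover
        return (f"EnergyBreakdown(U_bond={self.U_bond:.6g}, "
                f"U_bend={self.U_bend:.6g}, U_wall_fixed={self.U_wall_fixed:.6g}, "
                f"U_wall_mobile={self.U_wall_mobile:.6g}, "
                f"F_w_bun={self.F_w_bun:.6g}, F_w_m={self.F_w_m:.6g})")


def compute_forces(state, params: SimulationParams):
    """Forces on every monomer, total force on the mobile wall, and energies.

    Parameters
    ----------
    state : SystemState
        Current configuration.
    params : SimulationParams

    Returns
    -------
    forces : (cap, 3) ndarray
        Per-slot forces; entries for seed monomers are zeroed (seeds are
        immobile parts of the grafting wall) and inactive slots are zero.
    wall_force : float
        Total longitudinal force on the mobile wall: monomer reaction
        forces minus ``kappa_T L`` minus ``pA``.
    breakdown : EnergyBreakdown
    """
    from ._kernels import forces_kernel

    F = np.zeros_like(state.pos)
    out = forces_kernel(
        state.pos, state.owner, state.rank, state.fil, state.jn,
        params.Nf, state.L, F,
        params.d, params.ks, params.eps0, params.kappa_bend,
        params.eps_w, params.s_c)
    U_bond, U_bend, U_wf, U_wm, F_bun, F_m = out
    wall_force = F_bun + F_m - params.kappa_T * state.L - params.pA
    br = EnergyBreakdown(U_bond, U_bend, U_wf, U_wm, F_bun, F_m)
    return F, wall_force, br
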