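"""Grand-canonical control of the free-monomer chemical potential.

Insertion and deletion attempts, chosen with equal probability, run on a
Poisson clock of rate ``nu_GC``.  For an ideal confined gas the activity
equals the imposed density ``rho1 = rho_hat1 * rho1c``, and the standard
acceptance rules are

    insert: min(1, rho1 V exp(-beta dU) / (N1 + 1))
    delete: min(1, N1 exp(+beta dU) / (rho1 V))

with ``V = A L`` the instantaneous chamber volume and ``dU`` the wall
potential energy of the exchanged monomer (the only interaction a free
monomer has).  A monomer that is chemically reactive — within ``r_c`` of
a filament tip — is never inserted or deleted: the exclusion is applied
symmetrically to both directions so the reservoir chain and the reaction
chain stay jointly reversible.  Inserted monomers draw Maxwell-Boltzmann
velocities.

The second chamber is not simulated: its free monomers act on the wall
only through the mean pressure force ``p A``.
"""

from __future__ import annotations

import math

from .params import SimulationParams
from .state import SystemState
from .energetics import wall_energy

__all__ = ["chamber2_pressure", "insertion_acceptance", "deletion_acceptance",
           "gc_summary"]


def chamber2_pressure(params: SimulationParams) -> float:
    """Ideal free-monomer gas pressure ``p = kBT rho1`` [kBT/d^3].

    Equivalently ``(kBT/d^3) exp(beta mu1*)``; the wall equation of
    motion receives the constant force ``-p A``.
    """
    return params.kBT * params.rho1


def _wall_dU(params: SimulationParams, x: float, L: float) -> float:
    dU = 0.0
    if x <= params.s_c:
        dU += float(wall_energy(x, params))
    if L - x <= params.s_c:
        dU += float(wall_energy(L - x, params))
    return dU


def insertion_acceptance(params: SimulationParams, x: float, L: float,
                         N1: int) -> float:
    """Acceptance probability for inserting at longitudinal position ``x``."""
    V = params.A * L
    dU = _wall_dU(params, x, L)
    return min(1.0, params.rho1 * V * math.exp(-params.beta * dU) / (N1 + 1))


def deletion_acceptance(params: SimulationParams, x: float, L: float,
                        N1: int) -> float:
    """Acceptance probability for deleting a free monomer at ``x``."""
    if N1 <= 0:
        return 0.0
    V = params.A * L
    dU = _wall_dU(params, x, L)
    return min(1.0, N1 * math.exp(params.beta * dU) / (params.rho1 * V))


def gc_summary(counters) -> dict:
    """Reservoir move statistics from the run counters."""
    gc = counters.gc
    out = {
        "insert_attempts": int(gc[0]), "insert_accepted": int(gc[1]),
        "insert_refused_reactive": int(gc[2]),
        "delete_attempts": int(gc[3]), "delete_accepted": int(gc[4]),
        "delete_refused_reactive": int(gc[5]),
        "delete_refused_empty": int(gc[6]),
    }
    att = out["insert_attempts"] + out["delete_attempts"]
    out["acceptance"] = ((out["insert_accepted"] + out["delete_accepted"]) / att
                        if att else float("nan"))
    return out
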