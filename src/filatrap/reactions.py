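"""Single-monomer (de)polymerization Monte Carlo at filament tips.

Each filament carries two independent Poisson clocks of rate ``nu``, one
per reaction direction.  A polymerization attempt captures, in place, a
real free monomer chosen uniformly among the ``N_r`` candidates inside
the sphere of radius ``r_c`` around the tip; a depolymerization attempt
releases the tip monomer in place (position and velocity retained).  The
acceptance pair

    poly:   min(1, N_r exp(-beta * el_new))
    depol:  exp(-beta eps0) * min(1, exp(+beta * el_tip) / N_r')

with ``el`` the spring + bend energy of the created/removed tip bond and
``N_r'`` the candidate count around the new tip after release (which
includes the freed monomer itself), satisfies detailed balance with
respect to the Boltzmann measure: the pointwise ratio equals
``N_r exp(-beta dU)`` with ``dU = -eps0 + el``.  Consequences:

* an unconfined filament in the grand-canonical bath has stationary size
  distribution ``P_{i+1}/P_i = rho1 K0 = rho_hat1``;
* the bulk effective rates are ``W0 ~= nu exp(-beta eps0)`` (slightly
  below, through the ``1/N_r'`` count correction) and ``U0 = rho_hat1 W0``;
* near the wall, polymerization is gated by the Brownian-ratchet
  mechanism: candidates in the shrinking gap are never in
  bond-compatible positions, so ``exp(-beta el_new)`` vanishes.

A reversibility guard rejects a release whose freed monomer would lie
outside the reaction sphere of the new tip, so every accepted move is
the exact reverse of a possible capture.  Seeds are immutable:
depolymerization at ``j_n = 2`` is always rejected.

The moves themselves execute inside the dynamics kernel; this module
exposes the same rules on explicit states for analysis and testing.
"""

from __future__ import annotations

import math

import numpy as np

from .params import SimulationParams
from .state import SystemState
from ._kernels import _is_reactive, _count_candidates

__all__ = ["is_reactive", "candidate_count", "poly_acceptance",
           "depoly_acceptance", "schedule_reactions", "tip_elastic_energy"]


def is_reactive(state: SystemState, slot: int) -> bool:
    """True iff free monomer ``slot`` lies within ``r_c`` of any filament tip."""
    if state.owner[slot] != 0:
        raise ValueError(f"slot {slot} is not a free monomer (owner="
                         f"{state.owner[slot]})")
    p = state.params
    x, y, z = state.pos[slot]
    return bool(_is_reactive(state.pos, state.fil, state.jn, p.Nf,
                             x, y, z, p.r_c, p.L_prime))


def candidate_count(state: SystemState, n: int) -> int:
    """Number of free monomers inside the reaction sphere of tip ``n``."""
    p = state.params
    it = state.fil[n, state.jn[n] - 1]
    tx, ty, tz = state.pos[it]
    return int(_count_candidates(state.pos, state.free_list, state.N1,
                                 tx, ty, tz, p.r_c, p.L_prime, -1))


def tip_elastic_energy(state: SystemState, n: int, point: np.ndarray) -> float:
    """Spring + bend energy of a bond from tip ``n`` to ``point`` [kBT].

    ``point`` must already be the image nearest the tip.
    """
    p = state.params
    jnn = int(state.jn[n])
    it = state.fil[n, jnn - 1]
    ip = state.fil[n, jnn - 2]
    b2 = np.asarray(point, dtype=float) - state.pos[it]
    r = float(np.linalg.norm(b2))
    b1 = state.pos[it] - state.pos[ip]
    c = float(b1 @ b2 / (np.linalg.norm(b1) * r))
    return 0.5 * p.ks * (r - p.d) ** 2 + p.kappa_bend * (1.0 - c)


def poly_acceptance(params: SimulationParams, n_r: int, el_new: float) -> float:
    """Acceptance probability of a capture with ``n_r`` candidates."""
    if n_r <= 0:
        return 0.0
    return min(1.0, n_r * math.exp(-params.beta * el_new))


def depoly_acceptance(params: SimulationParams, n_r_after: int,
                      el_tip: float) -> float:
    """Acceptance probability of a release; ``n_r_after`` counts the
    candidates around the new tip including the freed monomer."""
    return (math.exp(-params.beta * params.eps0)
            * min(1.0, math.exp(params.beta * el_tip) / n_r_after))


def schedule_reactions(state: SystemState) -> np.ndarray:
    """Redraw the 2 Nf exponential reaction waiting times (rate ``nu`` each).

    Returns the pending event-time vector; entry 0 is the reservoir
    clock (untouched), entries 1..Nf the polymerization clocks and
    Nf+1..2Nf the depolymerization clocks.
    """
    p = state.params
    for q in range(1, 2 * p.Nf + 1):
        state.evt[q] = state.t + state.rng_react.exponential(1.0 / p.nu)
    return state.evt
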