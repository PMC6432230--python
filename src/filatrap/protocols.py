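"""Reusable measurement protocols.

``bulk_chemistry_run`` measures the bulk (plateau) effective reaction
rates of a single grafted filament in the grand-canonical bath with the
wall parked far away.  Under supercritical conditions the filament grows
on average, so the measurement is split into independent segments: each
starts from a short straight chain and runs until the filament
approaches the fixed wall, at which point a fresh segment begins.  All
segments share the same residence/attempt/success counters, and the
plateau rates are the residence-time-weighted estimators restricted to
the wall-free region (m <= -1 for depolymerization, m <= -2 for
polymerization).
"""

from __future__ import annotations

import numpy as np

from .params import SimulationParams
from .simulation import Simulation
from .state import Counters, build_initial_state
from .observables import rates_table, plateau_rates

__all__ = ["bulk_chemistry_run", "strip_free_monomers", "bare_wall_state",
           "trap_equilibrium_run", "two_state_toy", "two_state_quadrature"]


def strip_free_monomers(state) -> None:
    """Remove every free monomer from a state (calibration runs)."""
    while state.N1 > 0:
        a = state.N1 - 1
        i = state.free_list[a]
        state.owner[i] = -1
        state.slot_stack[state.icounts[1]] = i
        state.icounts[1] += 1
        state.icounts[0] -= 1


def bare_wall_state(params: SimulationParams, L0: float):
    """A state with only the trapped wall: bare seeds, no free monomers.

    Used for calibration runs of the wall Langevin dynamics (the bare
    seeds are immobile and, with the wall parked away from them, inert).
    """
    state = build_initial_state(params, L0)
    strip_free_monomers(state)
    return state


def trap_equilibrium_run(seed: int,
                         equilibration: float = 600.0,
                         production: float = 3500.0,
                         params: SimulationParams | None = None,
                         trace_dt: float = 0.2,
                         jcap_extra: int = 45):
    """Single-filament optical-trap equilibrium run.

    The filament starts as a straight chain two monomers short of the
    crossover size at the mean-field wall position L_H (equivalent to
    growing from a bare seed, at a fraction of the cost), the mobile
    wall then equilibrates for ``equilibration`` tauD, and counters are
    reset before a production run of ``production`` tauD.

    Returns (sim, trace).
    """
    from .theory import hill_theory
    p = (params or SimulationParams()).replace(seed=seed)
    L0 = hill_theory(p.Nf, p.kappa_T, p.rho_hat1, p.d, p.kBT)[1]
    j_init = max(2, int(L0 / p.d) - 1)
    state = build_initial_state(p, L0, j_init=j_init,
                                jcap=j_init + jcap_extra)
    sim = Simulation(p, state=state)
    sim.run(equilibration, wall_mobile=True, log_level=0, check=False)
    sim.counters.reset()
    trace = sim.run(production, wall_mobile=True, trace_dt=trace_dt,
                    log_level=0, check=False)
    return sim, trace


def _toy_params(seed: int) -> SimulationParams:
    # A deliberately soft bond (weak spring, weak bending, modest bond
    # energy, slow attempt clock) in a small box.  With the production
    # stiffness the binding volume is so small that persistent
    # state-to-state transitions are diffusion-limited and the chain
    # takes ~1e5 tauD to converge; the acceptance rules are
    # parameter-generic, so detailed balance is tested just as sharply
    # here with ~100x the transition statistics.
    return SimulationParams(Nf=1, A=9.0, ks=200.0, kappa_bend=100.0,
                            eps0=8.0, nu=1000.0, seed=seed)


def two_state_toy(seed: int, duration: float = 6000.0, L_box: float = 5.0):
    """Two-state reaction chain: filament j=2 <-> j=3 with one monomer.

    A bare seed and a single free monomer in a small box with a fixed
    far wall, reservoir off: the only stochastic moves besides the
    dynamics are capture and release at the seed tip.  Returns the
    measured occupancy ratio P(j=3)/P(j=2), the number of observed
    transitions and the sampled trace.
    """
    p = _toy_params(seed)
    state = build_initial_state(p, L_box, j_init=2, jcap=5, cap=16)
    strip_free_monomers(state)
    i = state.slot_stack[state.icounts[1] - 1]
    state.icounts[1] -= 1
    state.owner[i] = 0
    state.pos[i] = (L_box / 2.0, p.L_prime / 2.0, p.L_prime / 2.0)
    state.vel[i] = state.rng_place.normal(
        0.0, np.sqrt(p.kBT / p.M), size=3)
    state.free_list[0] = i
    state.free_pos[i] = 0
    state.icounts[0] = 1
    sim = Simulation(p, state=state, include_gas_pressure=False)
    sim.run(10.0, wall_mobile=False, reservoir=False, log_level=0,
            check=False)
    trace = sim.run(duration, wall_mobile=False, reservoir=False,
                    trace_dt=0.05, log_level=0, check=False)
    j = trace.j[:, 0]
    n3 = int((j == 3).sum())
    n2 = int((j == 2).sum())
    if n2 == 0 or n3 == 0:
        raise RuntimeError("toy chain never switched state")
    switches = int((np.diff(j) != 0).sum())
    return n3 / n2, switches, trace


def two_state_quadrature(L_box: float = 5.0):
    """Brute-force configurational-integral oracle for ``two_state_toy``.

    P(j=3)/P(j=2) = Z_bonded / Z_free with

    Z_free   = A * int_0^L exp[-beta (Uw(x) + Uw(L-x))] dx
    Z_bonded = e^(beta eps0) * 2 pi *
               int r^2 sin(t) exp[-beta (ks(r-d)^2/2 + kappa(1-cos t)
                                         + Uw(x3) + Uw(L-x3))] dr dt

    with x3 = d + r cos(t) the longitudinal position of the bonded
    monomer (the seed bond lies along +x) and r limited to the reaction
    radius, outside which capture/release moves are impossible.
    """
    from scipy.integrate import quad, dblquad
    from .energetics import _wall_energy
    p = _toy_params(0)

    def wall_factor(x):
        if x <= 0.0 or x >= L_box:
            return 0.0
        return np.exp(-p.beta * (_wall_energy(x, p.d, p.eps_w, p.s_c)
                                 + _wall_energy(L_box - x, p.d, p.eps_w,
                                                p.s_c)))

    z_free = p.A * quad(wall_factor, 0.0, L_box, limit=200)[0]

    def bonded(theta, r):
        x3 = p.d + r * np.cos(theta)
        el = (0.5 * p.ks * (r - p.d) ** 2
              + p.kappa_bend * (1.0 - np.cos(theta)))
        if el > 60.0:  # exp underflow guard
            return 0.0
        return r * r * np.sin(theta) * np.exp(-p.beta * el) * wall_factor(x3)

    inner = dblquad(bonded, 0.0, p.r_c, 0.0, np.pi,
                    epsabs=1e-12, epsrel=1e-9)[0]
    z_bonded = np.exp(p.beta * p.eps0) * 2.0 * np.pi * inner
    return z_bonded / z_free


def bulk_chemistry_run(seed: int,
                       duration: float = 2000.0,
                       L_box: float = 40.0,
                       j_start: int = 5,
                       j_stop: int = 30,
                       params: SimulationParams | None = None,
                       relax: float = 2.0,
                       collect_trace: bool = False):
    """Measure bulk effective (de)polymerization rates.

    Parameters
    ----------
    seed : int
        Master seed; segment k uses seed + k.
    duration : float
        Total chemistry-on simulation time [tauD] summed over segments.
    L_box : float
        Fixed wall position [d]; with ``j_stop`` well below ``L_box`` the
        filament tip never feels the wall (m stays <= -10).
    j_start, j_stop : int
        Segment start size and restart threshold.

    Returns
    -------
    result : dict
        U0, W0 (plateau rates [1/tauD]), their ratio, event counts,
        pooled counters and the m-resolved rate table.
    """
    p = (params or SimulationParams()).replace(Nf=1)
    counters = Counters()
    t_total = 0.0
    segment = 0
    traces = []
    while duration - t_total > max(relax, 100.0 * p.h):
        sp = p.replace(seed=seed + segment)
        state = build_initial_state(sp, L_box, j_init=j_start,
                                    jcap=j_stop + 8)
        sim = Simulation(sp, state=state)
        sim.counters = counters
        # let the fresh chain and gas decorrelate before counting
        sim.run(relax, wall_mobile=False, chemistry=False, log_level=0,
                check=False)
        q_before = counters.Q.sum()
        remaining = duration - t_total
        tr = sim.run(remaining, wall_mobile=False, j_stop=j_stop,
                     trace_dt=(0.1 if collect_trace else None),
                     log_level=0, check=False)
        if collect_trace and tr is not None:
            traces.append(tr)
        t_total += (counters.Q.sum() - q_before) * p.h
        segment += 1
        if segment > 10000:
            raise RuntimeError("segment restart limit exceeded")
    table = rates_table(counters, p.h)
    U0, W0, nU, nW = plateau_rates(table)
    return {
        "U0": U0, "W0": W0, "ratio": U0 / W0,
        "n_poly": nU, "n_depoly": nW,
        "segments": segment, "duration": t_total,
        "counters": counters, "table": table,
        "traces": traces,
    }
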