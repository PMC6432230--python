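"""Analytic rigid-filament references and characteristic time scales.

The mean-field (Hill) theory treats the bundle as Nf rigid living
filaments against a hard wall: the bundle exerts the polymerization
force ``F_H = Nf (kBT/d) ln rho_hat1`` independently of L, so a trap of
strength ``kappa_T`` equilibrates at ``L_H = F_H / kappa_T`` with
Gaussian fluctuations of width ``sigma_H = sqrt(kBT / kappa_T)``.
"""

from __future__ import annotations

import math

from .params import SimulationParams
from .energetics import bulk_equilibrium_constant

__all__ = ["hill_theory", "brownian_ratchet_velocity", "bulk_rates",
           "timescales", "theory_report"]


def hill_theory(Nf: int, kappa_T: float, rho_hat1: float,
                d: float = 1.0, kBT: float = 1.0):
    """Rigid-filament references ``(F_H, L_H, sigma_H)``.

    F_H [kBT/d] is the bundle polymerization force, L_H [d] the mean
    trap length and sigma_H [d] the wall fluctuation width.
    """
    if rho_hat1 <= 0 or kappa_T <= 0:
        raise ValueError("rho_hat1 and kappa_T must be positive")
    F_H = Nf * (kBT / d) * math.log(rho_hat1)
    L_H = F_H / kappa_T
    sigma_H = math.sqrt(kBT / kappa_T)
    return F_H, L_H, sigma_H


def brownian_ratchet_velocity(F_L: float, U0: float, W0: float,
                              d: float = 1.0, kBT: float = 1.0) -> float:
    """Stationary wall velocity of the fast-diffusion Brownian ratchet.

    ``v(F_L) = d [U0 exp(-d F_L / kBT) - W0]``: the exponential is the
    probability that wall fluctuations open a gap of one monomer size
    against the load F_L.  Stalls at ``F_L = (kBT/d) ln(U0/W0)``.
    """
    if U0 < 0 or W0 < 0:
        raise ValueError("rates must be non-negative")
    return d * (U0 * math.exp(-d * F_L / kBT) - W0)


def bulk_rates(params: SimulationParams | None = None):
    """Bulk effective rates ``(U0, W0)`` [1/tauD] implied by the attempt
    rate: ``W0 ~= nu exp(-beta eps0)`` and ``U0 = rho_hat1 W0``."""
    p = params or SimulationParams()
    W0 = p.nu * math.exp(-p.beta * p.eps0)
    return p.rho_hat1 * W0, W0


def timescales(params: SimulationParams | None = None) -> dict:
    """Characteristic time scales [tauD] and the overdamping check.

    tau_s, tau_b : stiffest bond-stretching / bending periods
    tau_fm_in, tau_fm : free-monomer inertial and diffusion times
    tau_w_in, tau_T : wall inertial time and bare trap period
    tau_chem : mean time between bulk depolymerization events, 1/W0
    overdamped : tau_w_in^2 <= Mw / (4 kappa_T), i.e. the bare wall in
        the trap relaxes without oscillating
    """
    p = params or SimulationParams()
    U0, W0 = bulk_rates(p)
    tau_win = p.Mw / p.zeta_w
    return {
        "tau_s": 2.0 * math.pi * math.sqrt(p.M / p.ks),
        "tau_b": 2.0 * math.pi * math.sqrt(p.M * p.d ** 2 / (2.0 * p.kappa_bend)),
        "tau_fm_in": p.M / p.zeta,
        "tau_fm": p.d ** 2 * p.zeta / p.kBT,
        "tau_w_in": tau_win,
        "tau_T": 2.0 * math.pi * math.sqrt(p.Mw / p.kappa_T),
        "tau_D": p.zeta_w * p.d ** 2 / p.kBT,
        "tau_chem": 1.0 / W0,
        "W0": W0,
        "U0": U0,
        "overdamped": tau_win ** 2 <= p.Mw / (4.0 * p.kappa_T),
    }


def theory_report(params: SimulationParams | None = None) -> dict:
    """All analytic quantities for a parameter set, in reduced units."""
    p = params or SimulationParams()
    K0, rho1c, mu1c_star = bulk_equilibrium_constant(p)
    F_H, L_H, sigma_H = hill_theory(p.Nf, p.kappa_T, p.rho_hat1, p.d, p.kBT)
    out = {
        "K0": K0,
        "rho1c": rho1c,
        "mu1c_star": mu1c_star,
        "mu1_star": p.mu1_star,
        "rho1": p.rho1,
        "pressure": p.pressure,
        "pA": p.pA,
        "F_H": F_H,
        "L_H": L_H,
        "sigma_H": sigma_H,
    }
    out.update(timescales(p))
    return out
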