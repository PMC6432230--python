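"""Model parameters in reduced units.

The natural units of the model are the monomer size ``d``, the thermal
energy ``kBT`` and the wall diffusion time ``tauD = zeta_w * d**2 / kBT``.
All three equal 1 by construction with the default frictions.  Masses are
expressed in ``tauD**2 kBT / d**2``, frictions in ``tauD kBT / d**2``,
energies in ``kBT`` and rates in ``1/tauD``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["SimulationParams", "load_config", "save_config"]

#: minimum of the 9-3 wall potential, where it is truncated
S_CUTOFF = 3.0 ** (1.0 / 6.0)


@dataclass
class SimulationParams:
    """All model constants and run controls.

    Defaults are the model-column values of the reference parameter set
    (single filament in a trap of strength ``kappa_T = 0.019375 kBT/d^2``
    at reduced free-monomer density 2.5).
    """

    d: float = 1.0              # monomer size [d]
    kBT: float = 1.0            # thermal energy [kBT]
    M: float = 3.556e-3         # monomer mass [tauD^2 kBT/d^2]
    Mw: float = 1.0667e-2       # wall mass [tauD^2 kBT/d^2]
    zeta: float = 0.5           # monomer friction [tauD kBT/d^2]
    zeta_w: float = 1.0         # wall friction [tauD kBT/d^2]
    ks: float = 4000.0          # bond spring constant [kBT/d^2]
    kappa_bend: float = 5370.0  # bending stiffness [kBT]; = Lp/d
    eps0: float = 13.644143     # bond formation energy [kBT]
    eps_w: float = 0.1          # wall potential strength [kBT]
    kappa_T: float = 0.019375   # trap strength [kBT/d^2]
    A: float = 36.0             # transverse area [d^2]
    Nf: int = 1                 # number of grafted filaments (1 or 2*l^2)
    rho_hat1: float = 2.5       # reduced free-monomer density rho1/rho1c
    nu: float = 7.1e4           # reaction attempt rate per direction [1/tauD]
    nu_GC: float = 187.5        # reservoir exchange attempt rate [1/tauD]
    h: float = 5.33e-5          # integration time step [tauD]
    r_c: float = 1.5            # reaction-region radius [d]
    seed: int = 0               # master RNG seed
    L_R: float | None = None    # total two-chamber box length (documentation only)

    def __post_init__(self) -> None:
        for name in ("d", "kBT", "M", "Mw", "zeta", "zeta_w", "ks",
                     "kappa_bend", "eps0", "eps_w", "kappa_T", "A",
                     "nu", "nu_GC", "h", "r_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if self.rho_hat1 <= 0:
            raise ValueError("rho_hat1 must be positive")
        n = self.Nf
        if not (n == 1 or _is_2l2(n)):
            raise ValueError(
                f"Nf={n} invalid: the seed lattice requires Nf == 1 or "
                "Nf == 2*l**2 for an integer l (body-centered square lattice)")

    # ---- derived quantities -------------------------------------------------

    @property
    def beta(self) -> float:
        return 1.0 / self.kBT

    @property
    def Lp(self) -> float:
        """Persistence length [d]: kappa_bend * d / kBT."""
        return self.kappa_bend * self.d / self.kBT

    @property
    def s_c(self) -> float:
        """Wall potential cutoff 3^(1/6) d (potential minimum)."""
        return S_CUTOFF * self.d

    @property
    def L_prime(self) -> float:
        """Transverse box edge sqrt(A)."""
        return math.sqrt(self.A)

    @property
    def K0(self) -> float:
        """Bulk chemical equilibrium constant [d^3]."""
        from .energetics import bulk_equilibrium_constant
        return bulk_equilibrium_constant(self)[0]

    @property
    def rho1c(self) -> float:
        """Critical free-monomer density 1/K0 [d^-3]."""
        return 1.0 / self.K0

    @property
    def mu1c_star(self) -> float:
        """Critical effective chemical potential kBT ln(rho1c d^3)."""
        return self.kBT * math.log(self.rho1c * self.d ** 3)

    @property
    def mu1_star(self) -> float:
        """Imposed effective chemical potential mu1c* + kBT ln rho_hat1."""
        return self.mu1c_star + self.kBT * math.log(self.rho_hat1)

    @property
    def rho1(self) -> float:
        """Imposed free-monomer density rho_hat1 * rho1c [d^-3]."""
        return self.rho_hat1 * self.rho1c

    @property
    def pressure(self) -> float:
        """Ideal free-monomer gas pressure kBT * rho1 [kBT/d^3]."""
        return self.kBT * self.rho1

    @property
    def pA(self) -> float:
        """Mean second-chamber pressure force on the mobile wall [kBT/d]."""
        return self.pressure * self.A

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationParams":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "SimulationParams":
        d = self.to_dict()
        d.update(kwargs)
        return SimulationParams.from_dict(d)


def _is_2l2(n: int) -> bool:
    if n < 2 or n % 2:
        return False
    l = round(math.sqrt(n / 2))
    return 2 * l * l == n


def load_config(path: str | Path) -> SimulationParams:
    """Read a flat key-value YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must be a flat mapping")
    return SimulationParams.from_dict(data)


def save_config(params: SimulationParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
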