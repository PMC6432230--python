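"""System state: topology bookkeeping, seed geometry, initial configurations.

Each monomer carries a pair of dynamical topological indices (n, k):
``n = 0`` marks a free monomer, ``n >= 1`` the filament it belongs to and
``k`` its 1-based rank along that filament.  Ranks 1 and 2 are the two
immobile seed monomers grafting the filament normally to the fixed wall;
a filament size ``j_n`` is therefore never below 2.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import SimulationParams
from ._kernels import M_OFFSET, M_SIZE

__all__ = ["Topology", "SystemState", "build_seed_layout",
           "build_initial_state", "Counters"]


@dataclass
class Topology:
    """Seed geometry and per-filament bookkeeping."""

    h_n: np.ndarray        # (Nf+1,) longitudinal seed offsets [d]; entry 0 unused
    seed_xy: np.ndarray    # (Nf+1, 2) transverse seed coordinates [d]

    @property
    def Nf(self) -> int:
        return len(self.h_n) - 1


def build_seed_layout(params: SimulationParams, staggered: bool = True) -> Topology:
    """Place filament seeds on a body-centered square lattice.

    For ``Nf = 2 l**2`` the grafting plane carries ``l**2`` corner sites
    and ``l**2`` center sites of a lattice with unit cell ``a = L'/l``.
    The "homogeneous bundle" staggering offsets seed ``n`` longitudinally
    by ``h_n = (n - Nf/2 - 1/2) d / Nf``: Nf equally spaced phases with
    step ``d/Nf``, symmetric about 0, so the wall contacts of the
    filaments are uniformly dephased over one monomer length.  For a
    single filament ``h_1 = 0`` and the seed sits at the cell center.
    """
    Nf = params.Nf
    h_n = np.zeros(Nf + 1)
    seed_xy = np.zeros((Nf + 1, 2))
    if Nf == 1:
        seed_xy[1] = (params.L_prime / 2.0, params.L_prime / 2.0)
        return Topology(h_n, seed_xy)

    l = round(math.sqrt(Nf / 2))
    if 2 * l * l != Nf:
        raise ValueError(
            f"Nf={Nf} invalid: the seed lattice requires Nf == 2*l**2")
    a = params.L_prime / l
    n = 1
    for ix in range(l):          # corner sites
        for iy in range(l):
            seed_xy[n] = (ix * a, iy * a)
            n += 1
    for ix in range(l):          # center sites
        for iy in range(l):
            seed_xy[n] = ((ix + 0.5) * a, (iy + 0.5) * a)
            n += 1
    if staggered:
        for n in range(1, Nf + 1):
            h_n[n] = (n - Nf / 2.0 - 0.5) * params.d / Nf
    return Topology(h_n, seed_xy)


@dataclass
class Counters:
    """Residence, attempt and success counters resolved by relative size m.

    Index ``m + M_OFFSET``; the residence counter ``Q`` is incremented
    once per filament per time step, the attempt/success counters on
    reaction events tagged with the pre-event m.
    """

    Q: np.ndarray = field(default_factory=lambda: np.zeros(M_SIZE, dtype=np.int64))
    attU: np.ndarray = field(default_factory=lambda: np.zeros(M_SIZE, dtype=np.int64))
    attW: np.ndarray = field(default_factory=lambda: np.zeros(M_SIZE, dtype=np.int64))
    sucU: np.ndarray = field(default_factory=lambda: np.zeros(M_SIZE, dtype=np.int64))
    sucW: np.ndarray = field(default_factory=lambda: np.zeros(M_SIZE, dtype=np.int64))
    # insertion att/acc/refused-reactive, deletion att/acc/refused-reactive/empty
    gc: np.ndarray = field(default_factory=lambda: np.zeros(7, dtype=np.int64))

    m_offset: int = M_OFFSET

    def reset(self) -> None:
        for a in (self.Q, self.attU, self.attW, self.sucU, self.sucW, self.gc):
            a[:] = 0

    @property
    def gc_acceptance(self) -> float:
        att = self.gc[0] + self.gc[3]
        return float(self.gc[1] + self.gc[4]) / att if att else float("nan")


class SystemState:
    """Complete dynamical state of the primary chamber."""

    def __init__(self, params: SimulationParams, topology: Topology,
                 cap: int, jcap: int, seed: int | None = None):
        self.params = params
        self.topology = topology
        Nf = params.Nf
        self.pos = np.zeros((cap, 3))
        self.vel = np.zeros((cap, 3))
        self.owner = np.full(cap, -1, dtype=np.int64)
        self.rank = np.zeros(cap, dtype=np.int64)
        self.fil = np.zeros((Nf + 1, jcap), dtype=np.int64)
        self.jn = np.zeros(Nf + 1, dtype=np.int64)
        self.free_list = np.zeros(cap, dtype=np.int64)
        self.free_pos = np.zeros(cap, dtype=np.int64)
        self.slot_stack = np.zeros(cap, dtype=np.int64)
        # [n_free, n_slot_stack, trace_rows, event_rows]
        self.icounts = np.zeros(4, dtype=np.int64)
        self.L = 0.0
        self.Ldot = 0.0
        self.t = 0.0
        # labelled, independent RNG streams
        ss = np.random.SeedSequence(params.seed if seed is None else seed)
        s_thermo, s_react, s_gc, s_place = ss.spawn(4)
        self.rng_thermo = np.random.default_rng(s_thermo)
        self.rng_react = np.random.default_rng(s_react)
        self.rng_gc = np.random.default_rng(s_gc)
        self.rng_place = np.random.default_rng(s_place)
        # pending Poisson event times: [0] reservoir, [1..Nf] poly, [Nf+1..2Nf] depol
        self.evt = np.full(2 * Nf + 1, np.inf)

    # ---- convenience views --------------------------------------------------

    @property
    def N1(self) -> int:
        """Number of free monomers."""
        return int(self.icounts[0])

    @property
    def n_free_slots(self) -> int:
        return int(self.icounts[1])

    @property
    def Nt(self) -> int:
        """Total monomer count (filament members + free)."""
        return int(self.jn[1:].sum() + self.icounts[0])

    def filament_positions(self, n: int) -> np.ndarray:
        return self.pos[self.fil[n, :self.jn[n]]]

    def free_positions(self) -> np.ndarray:
        return self.pos[self.free_list[:self.N1]]

    def schedule_events(self) -> None:
        """(Re)draw all pending Poisson event times from the current clock."""
        p = self.params
        self.evt[0] = self.t + self.rng_gc.exponential(1.0 / p.nu_GC)
        for q in range(1, 2 * p.Nf + 1):
            self.evt[q] = self.t + self.rng_react.exponential(1.0 / p.nu)

    def check_invariants(self) -> None:
        """Raise if topology bookkeeping is inconsistent."""
        seen = set()
        for n in range(1, self.params.Nf + 1):
            jn = int(self.jn[n])
            assert jn >= 2, f"filament {n} has size {jn} < 2"
            for k in range(jn):
                i = int(self.fil[n, k])
                assert self.owner[i] == n and self.rank[i] == k + 1, \
                    f"slot {i} owner/rank mismatch for ({n},{k + 1})"
                assert i not in seen, f"slot {i} appears twice"
                seen.add(i)
        for a in range(self.N1):
            i = int(self.free_list[a])
            assert self.owner[i] == 0, f"free-list slot {i} not free"
            assert self.free_pos[i] == a
            assert i not in seen, f"slot {i} appears twice"
            seen.add(i)
        assert len(seen) == self.Nt
        if self.N1:
            # soft walls permit brief skin excursions but never a crossing
            xs = self.pos[self.free_list[:self.N1], 0]
            s_c = self.params.s_c
            assert xs.min() > -s_c and xs.max() < self.L + s_c, \
                "free monomer beyond the hard position bound"

    # ---- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint the full state, including RNG streams and event clocks."""
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "SystemState":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        if not isinstance(state, SystemState):
            raise ValueError(f"{path} is not a filatrap checkpoint")
        return state


def build_initial_state(params: SimulationParams, L0: float,
                        staggered: bool = True,
                        j_init: int = 2,
                        kBT_init: float | None = None,
                        cap: int | None = None,
                        jcap: int | None = None) -> SystemState:
    """Bare seeds plus a homogeneous ideal free-monomer gas, wall at ``L0``.

    Filaments start with ``j_init`` monomers (2 = bare seed; larger values
    build a straight chain along +x, useful for restarts).  Free monomers
    are placed as a homogeneous spatial Poisson process at density
    ``rho1 = rho_hat1 * rho1c`` in the slab ``0 < x < L0``, with
    Maxwell-Boltzmann velocities; the wall starts at rest.
    """
    p = params
    if L0 <= 2 * p.d + p.s_c:
        raise ValueError(f"L0={L0} too small to contain the grafted seeds")
    if j_init < 2:
        raise ValueError("filaments are restricted to j >= 2")
    topo = build_seed_layout(p, staggered=staggered)
    Nf = p.Nf
    expected_N1 = p.rho1 * p.A * L0
    if jcap is None:
        jcap = int(L0 / p.d) + 40
    if cap is None:
        cap = int(3 * expected_N1) + Nf * jcap + 64
    state = SystemState(p, topo, cap=cap, jcap=jcap)
    kT = p.kBT if kBT_init is None else kBT_init
    rng = state.rng_place

    slot = 0
    for n in range(1, Nf + 1):
        hx, (sy, sz) = topo.h_n[n], topo.seed_xy[n]
        for k in range(1, j_init + 1):
            state.pos[slot] = (hx + (k - 1) * p.d, sy, sz)
            if k > 2 and kT > 0:
                state.vel[slot] = rng.normal(0.0, math.sqrt(kT / p.M), size=3)
            state.owner[slot] = n
            state.rank[slot] = k
            state.fil[n, k - 1] = slot
            slot += 1
        state.jn[n] = j_init

    n1 = rng.poisson(expected_N1)
    if slot + n1 > cap:
        raise ValueError("capacity too small for the drawn free-monomer count")
    from .energetics import _wall_energy
    for a in range(n1):
        # longitudinal coordinate from the equilibrium barometric profile
        # rho(x) ~ exp[-beta Uw] near each wall (rejection sampling); a
        # uniform draw can land in the repulsive core and destabilize the
        # first integration steps
        while True:
            x = rng.uniform(0.0, L0)
            dU = (_wall_energy(x, p.d, p.eps_w, p.s_c)
                  + _wall_energy(L0 - x, p.d, p.eps_w, p.s_c))
            if rng.random() < math.exp(-p.beta * dU):
                break
        state.pos[slot] = (x,
                           rng.uniform(0.0, p.L_prime),
                           rng.uniform(0.0, p.L_prime))
        if kT > 0:
            state.vel[slot] = rng.normal(0.0, math.sqrt(kT / p.M), size=3)
        state.owner[slot] = 0
        state.free_list[a] = slot
        state.free_pos[slot] = a
        slot += 1
    state.icounts[0] = n1

    n_stack = 0
    for i in range(cap - 1, slot - 1, -1):
        state.slot_stack[n_stack] = i
        n_stack += 1
    state.icounts[1] = n_stack

    state.L = float(L0)
    state.Ldot = 0.0
    state.t = 0.0
    state.schedule_events()
    return state
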