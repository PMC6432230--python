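"""Simulation driver: Langevin dynamics interleaved with Poisson-clocked
reaction and reservoir events.

The integrator is the two-Gaussian stochastic velocity-Verlet scheme of
Vanden-Eijnden and Ciccotti: a position update containing the
O(h^{3/2}) displacement noise, a force recomputation and a closing
velocity update; with friction and noise switched off it reduces exactly
to velocity Verlet.  Reaction and reservoir events are scheduled as
independent exponential clocks (rate ``nu`` per direction per filament,
``nu_GC`` for the reservoir) and executed at the first step boundary at
or after their scheduled time; simultaneous events run in time order,
reactions before reservoir moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import KernelParams, run_kernel, EV_FIELDS
from .params import SimulationParams
from .state import SystemState, Counters, build_initial_state

__all__ = ["Trace", "Simulation", "STATUS_NAMES"]

STATUS_NAMES = {
    _kernels.OK: "ok",
    _kernels.J_STOP: "j_stop reached",
    _kernels.JCAP_FULL: "filament capacity exhausted",
    _kernels.SLOTS_FULL: "monomer slot capacity exhausted",
    _kernels.NOT_FINITE: "non-finite coordinate or energy (time step too large?)",
    _kernels.TRACE_FULL: "trace buffer full",
}


@dataclass
class Trace:
    """Uniformly strided time series of the slow observables.

    ``E`` columns: U_bond, U_bend, U_wall_fixed, U_wall_mobile,
    F_w_bun (bundle force on the wall), F_w_m (gas force on the wall).
    """

    t: np.ndarray
    L: np.ndarray
    Ldot: np.ndarray
    N1: np.ndarray
    j: np.ndarray       # (n_rows, Nf)
    X: np.ndarray       # longitudinal end-to-end component per filament
    R_perp: np.ndarray  # transverse end-to-end modulus per filament
    E: np.ndarray       # (n_rows, 6)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def I(self) -> np.ndarray:
        """Bundle mean size sum_n j_n / Nf per sample."""
        return self.j.mean(axis=1)

    def to_dataframe(self):
        import pandas as pd
        Nf = self.j.shape[1]
        data = {"t": self.t, "L": self.L, "Ldot": self.Ldot, "N1": self.N1}
        for n in range(Nf):
            data[f"j{n + 1}"] = self.j[:, n]
        for n in range(Nf):
            data[f"X{n + 1}"] = self.X[:, n]
        for n in range(Nf):
            data[f"Rperp{n + 1}"] = self.R_perp[:, n]
        for i, c in enumerate(("U_bond", "U_bend", "U_wall_fixed",
                               "U_wall_mobile", "F_w_bun", "F_w_m")):
            data[c] = self.E[:, i]
        return pd.DataFrame(data)

    @staticmethod
    def concatenate(traces: list["Trace"]) -> "Trace":
        return Trace(*[np.concatenate([getattr(tr, f) for tr in traces])
                       for f in ("t", "L", "Ldot", "N1", "j", "X", "R_perp", "E")])


class Simulation:
    """A living-filament bundle pressing on a harmonically loaded wall.

    Parameters
    ----------
    params : SimulationParams
    state : SystemState, optional
        Resume from an existing state; otherwise one is built with the
        wall fixed at ``L0``.
    L0 : float, optional
        Initial wall position [d].  Defaults to the rigid-filament
        mean-field value ``F_H / kappa_T``.
    include_gas_pressure : bool
        Apply the mean second-chamber pressure force ``-pA`` to the wall.
    """

    def __init__(self, params: SimulationParams,
                 state: SystemState | None = None,
                 L0: float | None = None,
                 staggered: bool = True,
                 j_init: int = 2,
                 include_gas_pressure: bool = True,
                 cap: int | None = None,
                 jcap: int | None = None):
        self.params = params
        if state is None:
            if L0 is None:
                from .theory import hill_theory
                L0 = hill_theory(params.Nf, params.kappa_T,
                                 params.rho_hat1, params.d, params.kBT)[1]
            state = build_initial_state(params, L0, staggered=staggered,
                                        j_init=j_init, cap=cap, jcap=jcap)
        self.state = state
        self.counters = Counters()
        self.include_gas_pressure = include_gas_pressure
        self.event_log: list[np.ndarray] = []
        self.last_status = _kernels.OK

    def _kernel_params(self) -> KernelParams:
        p = self.params
        return KernelParams(
            d=float(p.d), beta=float(p.beta), kBT=float(p.kBT),
            M=float(p.M), Mw=float(p.Mw), zeta=float(p.zeta),
            zeta_w=float(p.zeta_w), ks=float(p.ks), eps0=float(p.eps0),
            kappa=float(p.kappa_bend), eps_w=float(p.eps_w),
            s_c=float(p.s_c), kappa_T=float(p.kappa_T),
            pA=float(p.pA) if self.include_gas_pressure else 0.0,
            Lprime=float(p.L_prime), nu=float(p.nu), nu_GC=float(p.nu_GC),
            h=float(p.h), r_c=float(p.r_c), rho1=float(p.rho1),
            A=float(p.A))

    def run(self, duration: float,
            wall_mobile: bool = True,
            thermostat: bool = True,
            chemistry: bool = True,
            reservoir: bool = True,
            trace_stride: int = 0,
            trace_dt: float | None = None,
            j_stop: int = 0,
            log_level: int = 1,
            max_log_events: int = 200_000,
            check: bool = True,
            callback=None,
            callback_dt: float | None = None) -> Trace | None:
        """Advance the system by ``duration`` [tauD].

        ``trace_dt`` (or ``trace_stride`` in steps) turns on recording of
        the observable trace.  ``j_stop > 0`` stops the run early when
        any filament reaches that size (used for bulk-rate segments).
        ``callback`` is invoked with the (read-only) state every
        ``callback_dt`` of simulated time, by splitting the run into
        segments at those boundaries.  Raises on integration failure
        unless the stop is a requested ``j_stop``.
        """
        if callback is not None:
            dt = callback_dt or duration
            traces = []
            remaining = duration
            while remaining > 0.5 * self.params.h:
                seg = min(dt, remaining)
                tr = self.run(seg, wall_mobile=wall_mobile,
                              thermostat=thermostat, chemistry=chemistry,
                              reservoir=reservoir, trace_stride=trace_stride,
                              trace_dt=trace_dt, j_stop=j_stop,
                              log_level=log_level,
                              max_log_events=max_log_events, check=check)
                if tr is not None:
                    traces.append(tr)
                callback(self.state)
                remaining -= seg
                if self.last_status == _kernels.J_STOP:
                    break
            return Trace.concatenate(traces) if traces else None
        p = self.params
        st = self.state
        n_steps = int(round(duration / p.h))
        if trace_dt is not None:
            trace_stride = max(1, int(round(trace_dt / p.h)))
        n_rec = n_steps // trace_stride + 2 if trace_stride > 0 else 0
        Nf = p.Nf

        tr_t = np.zeros(n_rec)
        tr_L = np.zeros(n_rec)
        tr_Ldot = np.zeros(n_rec)
        tr_N1 = np.zeros(n_rec, dtype=np.int64)
        tr_j = np.zeros((n_rec, Nf), dtype=np.int64)
        tr_X = np.zeros((n_rec, Nf))
        tr_R = np.zeros((n_rec, Nf))
        tr_E = np.zeros((n_rec, 6))
        ev = np.zeros((max_log_events if log_level > 0 else 1, EV_FIELDS))

        st.icounts[2] = 0
        st.icounts[3] = 0
        status, steps, L, Ldot, t = run_kernel(
            n_steps, self._kernel_params(), Nf,
            st.pos, st.vel, st.owner, st.rank, st.fil, st.jn,
            st.topology.h_n, st.free_list, st.free_pos, st.slot_stack,
            st.icounts, st.L, st.Ldot, st.t, st.evt,
            st.rng_thermo, st.rng_react, st.rng_gc,
            wall_mobile, thermostat, chemistry, reservoir,
            j_stop,
            self.counters.Q, self.counters.attU, self.counters.attW,
            self.counters.sucU, self.counters.sucW, self.counters.gc,
            trace_stride, tr_t, tr_L, tr_Ldot, tr_N1, tr_j, tr_X, tr_R, tr_E,
            log_level, ev)
        st.L, st.Ldot, st.t = L, Ldot, t
        self.last_status = status
        if log_level > 0 and st.icounts[3] > 0:
            self.event_log.append(ev[:st.icounts[3]].copy())
        if status not in (_kernels.OK, _kernels.J_STOP):
            raise RuntimeError(
                f"integration stopped after {steps} steps at t={t:.4g}: "
                f"{STATUS_NAMES.get(status, status)}")
        if check:
            st.check_invariants()
        if trace_stride > 0:
            r = int(st.icounts[2])
            return Trace(tr_t[:r], tr_L[:r], tr_Ldot[:r], tr_N1[:r],
                         tr_j[:r], tr_X[:r], tr_R[:r], tr_E[:r])
        return None

    def run_protocol(self, growth: float, equilibration: float,
                     production: float, trace_dt: float = 0.1,
                     log_level: int = 1) -> Trace:
        """Three-phase trap protocol.

        (1) wall fixed at its initial position while the filaments grow
        from bare seeds, (2) mobile-wall equilibration (discarded),
        (3) production with counters reset and the trace recorded.
        """
        if growth > 0:
            self.run(growth, wall_mobile=False, log_level=0)
        if equilibration > 0:
            self.run(equilibration, wall_mobile=True, log_level=0)
        self.counters.reset()
        return self.run(production, wall_mobile=True,
                        trace_dt=trace_dt, log_level=log_level)

    def event_dataframe(self):
        """Reaction event log as a DataFrame (t, filament, direction, m, dU, N_r, accepted)."""
        import pandas as pd
        if not self.event_log:
            return pd.DataFrame(
                columns=["t", "filament", "direction", "m", "dU", "N_r", "accepted"])
        arr = np.concatenate(self.event_log)
        df = pd.DataFrame(
            arr, columns=["t", "filament", "direction", "m", "dU", "N_r", "accepted"])
        for c in ("filament", "direction", "m", "N_r", "accepted"):
            df[c] = df[c].astype(int)
        return df
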