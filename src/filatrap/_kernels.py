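"""Numba kernels: forces, the stochastic integrator and the event loop.

Data layout
-----------
Monomers live in fixed-capacity slot arrays.  ``owner[i]`` is -1 for an
inactive slot, 0 for a free monomer and ``n >= 1`` for a member of
filament ``n``; ``rank[i]`` is the 1-based position along the filament.
``fil[n, k-1]`` maps the topological pair (n, k) to its slot.  Seed
monomers (ranks 1 and 2) are immobile.  Free monomers are listed in
``free_list[:n_free]`` with their list position in ``free_pos``;
inactive slots are stacked in ``slot_stack[:n_stack]``.

Filament monomer coordinates are kept unwrapped (contiguous along the
chain); free monomers are wrapped into [0, L') transversally.  Reaction
distances use the minimum image in y and z; when a capture is accepted
the candidate is shifted to the image nearest the tip so the chain stays
contiguous.

``icounts`` packs the mutable integer state:
[0] n_free, [1] n_stack, [2] trace rows written, [3] event-log rows.
"""

import math

import numpy as np
from numba import njit
from collections import namedtuple

from .energetics import _bond_energy, _bend_energy, _wall_energy, _wall_force_mag

# All-float physics constants for the kernels.
KernelParams = namedtuple("KernelParams", [
    "d", "beta", "kBT", "M", "Mw", "zeta", "zeta_w", "ks", "eps0",
    "kappa", "eps_w", "s_c", "kappa_T", "pA", "Lprime", "nu", "nu_GC",
    "h", "r_c", "rho1", "A",
])

# status codes returned by run_kernel
OK = 0
J_STOP = 1
JCAP_FULL = 2
SLOTS_FULL = 3
NOT_FINITE = 4
TRACE_FULL = 5

# half-width of the m-counter range; index = m + M_OFFSET, clipped
M_OFFSET = 100
M_SIZE = 2 * M_OFFSET + 1

# event-log record: t, n, direction(+1 poly/-1 depol), m, dU_elastic, N_r, accepted
EV_FIELDS = 7


@njit(cache=True, inline="always")
def _min_image(u, Lp):
    return u - Lp * math.floor(u / Lp + 0.5)


@njit(cache=True, fastmath=True)
def _forces(pos, F, rank, fil, jn, Nf, free_list, n_free, L, kp):
    """Fill F for all active slots; return energies, wall forces, error flag."""
    d, ks, eps0, kappa, eps_w, s_c = kp.d, kp.ks, kp.eps0, kp.kappa, kp.eps_w, kp.s_c
    U_bond = 0.0
    U_bend = 0.0
    U_wf = 0.0
    U_wm = 0.0
    F_bun = 0.0
    F_m = 0.0
    err = 0

    for n in range(1, Nf + 1):
        for k in range(jn[n]):
            i = fil[n, k]
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
    for a in range(n_free):
        i = free_list[a]
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0

    # intrafilament bond + bend terms
    for n in range(1, Nf + 1):
        jnn = jn[n]
        # bonds between ranks (k, k+1), k = 2 .. jnn-1  (seed bond 1-2 rigid)
        for k in range(2, jnn):
            i1 = fil[n, k - 1]
            i2 = fil[n, k]
            dx = pos[i2, 0] - pos[i1, 0]
            dy = pos[i2, 1] - pos[i1, 1]
            dz = pos[i2, 2] - pos[i1, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            U_bond += _bond_energy(r, d, ks, eps0)
            fm = -ks * (r - d) / r
            F[i2, 0] += fm * dx
            F[i2, 1] += fm * dy
            F[i2, 2] += fm * dz
            F[i1, 0] -= fm * dx
            F[i1, 1] -= fm * dy
            F[i1, 2] -= fm * dz
        # bends on triples (k, k+1, k+2), k = 1 .. jnn-2
        for k in range(1, jnn - 1):
            i1 = fil[n, k - 1]
            i2 = fil[n, k]
            i3 = fil[n, k + 1]
            b1x = pos[i2, 0] - pos[i1, 0]
            b1y = pos[i2, 1] - pos[i1, 1]
            b1z = pos[i2, 2] - pos[i1, 2]
            b2x = pos[i3, 0] - pos[i2, 0]
            b2y = pos[i3, 1] - pos[i2, 1]
            b2z = pos[i3, 2] - pos[i2, 2]
            n1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            n2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            e1x, e1y, e1z = b1x / n1, b1y / n1, b1z / n1
            e2x, e2y, e2z = b2x / n2, b2y / n2, b2z / n2
            c = e1x * e2x + e1y * e2y + e1z * e2z
            U_bend += _bend_energy(c, kappa)
            # F_i = kappa * d(cos)/d r_i
            g1x = (e2x - c * e1x) / n1
            g1y = (e2y - c * e1y) / n1
            g1z = (e2z - c * e1z) / n1
            g3x = (e1x - c * e2x) / n2
            g3y = (e1y - c * e2y) / n2
            g3z = (e1z - c * e2z) / n2
            F[i1, 0] -= kappa * g1x
            F[i1, 1] -= kappa * g1y
            F[i1, 2] -= kappa * g1z
            F[i3, 0] += kappa * g3x
            F[i3, 1] += kappa * g3y
            F[i3, 2] += kappa * g3z
            F[i2, 0] += kappa * (g1x - g3x)
            F[i2, 1] += kappa * (g1y - g3y)
            F[i2, 2] += kappa * (g1z - g3z)

    # wall terms: mobile filament members (rank >= 3) and free monomers
    for n in range(1, Nf + 1):
        for k in range(2, jn[n]):
            i = fil[n, k]
            x = pos[i, 0]
            if x <= 0.0:
                err = 1
            elif x <= s_c:
                U_wf += _wall_energy(x, d, eps_w, s_c)
                F[i, 0] += _wall_force_mag(x, d, eps_w, s_c)
            s2 = L - x
            if s2 <= 0.0:
                err = 1
            elif s2 <= s_c:
                U_wm += _wall_energy(s2, d, eps_w, s_c)
                fm = _wall_force_mag(s2, d, eps_w, s_c)
                F[i, 0] -= fm
                F_bun += fm
    for a in range(n_free):
        i = free_list[a]
        x = pos[i, 0]
        if x <= 0.0:
            err = 1
        elif x <= s_c:
            U_wf += _wall_energy(x, d, eps_w, s_c)
            F[i, 0] += _wall_force_mag(x, d, eps_w, s_c)
        s2 = L - x
        if s2 <= 0.0:
            err = 1
        elif s2 <= s_c:
            U_wm += _wall_energy(s2, d, eps_w, s_c)
            fm = _wall_force_mag(s2, d, eps_w, s_c)
            F[i, 0] -= fm
            F_m += fm

    return U_bond, U_bend, U_wf, U_wm, F_bun, F_m, err


@njit(cache=True)
def forces_kernel(pos, owner, rank, fil, jn, Nf, L, F,
                  d, ks, eps0, kappa, eps_w, s_c):
    """Standalone force evaluation used by the NumPy-facing API."""
    kp = KernelParams(d, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, ks, eps0, kappa,
                      eps_w, s_c, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 1.0)
    cap = pos.shape[0]
    free_list = np.empty(cap, dtype=np.int64)
    n_free = 0
    for i in range(cap):
        if owner[i] == 0:
            free_list[n_free] = i
            n_free += 1
    return _forces(pos, F, rank, fil, jn, Nf, free_list, n_free, L, kp)[:6]


@njit(cache=True, inline="always")
def _tip_elastic(pos, fil, n, jnn, cx, cy, cz, kp):
    """Spring + bend energy of a bond from tip (n, jnn) to point (cx, cy, cz)."""
    it = fil[n, jnn - 1]
    ip = fil[n, jnn - 2]
    dx = cx - pos[it, 0]
    dy = cy - pos[it, 1]
    dz = cz - pos[it, 2]
    r = math.sqrt(dx * dx + dy * dy + dz * dz)
    el = 0.5 * kp.ks * (r - kp.d) ** 2
    b1x = pos[it, 0] - pos[ip, 0]
    b1y = pos[it, 1] - pos[ip, 1]
    b1z = pos[it, 2] - pos[ip, 2]
    n1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    c = (b1x * dx + b1y * dy + b1z * dz) / (n1 * r)
    el += kp.kappa * (1.0 - c)
    return el, r


@njit(cache=True)
def _count_candidates(pos, free_list, n_free, tx, ty, tz, rc, Lp, skip):
    """Number of free monomers within rc of (tx,ty,tz), min-image in y,z."""
    cnt = 0
    rc2 = rc * rc
    for a in range(n_free):
        i = free_list[a]
        if i == skip:
            continue
        dx = pos[i, 0] - tx
        if dx > rc or dx < -rc:
            continue
        dy = _min_image(pos[i, 1] - ty, Lp)
        if dy > rc or dy < -rc:
            continue
        dz = _min_image(pos[i, 2] - tz, Lp)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= rc2:
            cnt += 1
    return cnt


@njit(cache=True)
def _is_reactive(pos, fil, jn, Nf, x, y, z, rc, Lp):
    """True if (x, y, z) lies within rc of any filament tip."""
    rc2 = rc * rc
    for n in range(1, Nf + 1):
        it = fil[n, jn[n] - 1]
        dx = x - pos[it, 0]
        if dx > rc or dx < -rc:
            continue
        dy = _min_image(y - pos[it, 1], Lp)
        dz = _min_image(z - pos[it, 2], Lp)
        if dx * dx + dy * dy + dz * dz <= rc2:
            return True
    return False


@njit(cache=True)
def _log_event(ev, icounts, t, n, direction, m, dU, n_r, accepted):
    row = icounts[3]
    if row < ev.shape[0]:
        ev[row, 0] = t
        ev[row, 1] = n
        ev[row, 2] = direction
        ev[row, 3] = m
        ev[row, 4] = dU
        ev[row, 5] = n_r
        ev[row, 6] = accepted
        icounts[3] = row + 1


@njit(cache=True, fastmath=True)
def run_kernel(n_steps, kp, Nf,
               pos, vel, owner, rank, fil, jn, hn,
               free_list, free_pos, slot_stack, icounts,
               L0, Ldot0, t0, evt,
               rng_thermo, rng_react, rng_gc,
               wall_mobile, thermostat, chemistry, reservoir,
               j_stop,
               Q, attU, attW, sucU, sucW, gcc,
               stride, tr_t, tr_L, tr_Ldot, tr_N1, tr_j, tr_X, tr_R, tr_E,
               log_level, ev):
    """Advance the system by ``n_steps`` integration steps.

    Returns (status, steps_done, L, Ldot, t).
    """
    cap = pos.shape[0]
    jcap = fil.shape[1]
    L = L0
    Ldot = Ldot0
    t = t0

    h = kp.h
    sh = math.sqrt(h)
    h32 = h * sh
    inv2s3 = 1.0 / (2.0 * math.sqrt(3.0))

    gm = kp.zeta / kp.M if thermostat else 0.0
    gw = kp.zeta_w / kp.Mw if thermostat else 0.0
    sm = math.sqrt(2.0 * kp.kBT * kp.zeta) / kp.M if thermostat else 0.0
    sw = math.sqrt(2.0 * kp.kBT * kp.zeta_w) / kp.Mw if thermostat else 0.0
    invM = 1.0 / kp.M
    invMw = 1.0 / kp.Mw

    exp_eps0 = math.exp(-kp.beta * kp.eps0)

    Fa = np.zeros((cap, 3))
    Fb = np.zeros((cap, 3))
    # per-slot noise/displacement buffers for the closing half of the step
    xi = np.zeros((cap, 3))
    Cb = np.zeros((cap, 3))

    res = _forces(pos, Fa, rank, fil, jn, Nf, free_list, icounts[0], L, kp)
    if res[6] != 0:
        return NOT_FINITE, 0, L, Ldot, t
    eU_bond, eU_bend, eU_wf, eU_wm, eF_bun, eF_m = res[:6]
    Fw = eF_bun + eF_m - kp.kappa_T * L - kp.pA
    xiw = 0.0
    Cw = 0.0

    status = OK
    step = 0
    while step < n_steps:
        # ---- position update (first half of the Vanden-Eijnden--Ciccotti step)
        for n in range(1, Nf + 1):
            for k in range(2, jn[n]):
                i = fil[n, k]
                for dd in range(3):
                    x1 = rng_thermo.standard_normal()
                    x2 = rng_thermo.standard_normal()
                    C = (0.5 * h * h * (Fa[i, dd] * invM - gm * vel[i, dd])
                         + sm * h32 * (0.5 * x1 + inv2s3 * x2))
                    xi[i, dd] = x1
                    Cb[i, dd] = C
                    pos[i, dd] += h * vel[i, dd] + C
        Lpr = kp.Lprime
        nf0 = icounts[0]
        for a in range(nf0):
            i = free_list[a]
            for dd in range(3):
                x1 = rng_thermo.standard_normal()
                x2 = rng_thermo.standard_normal()
                C = (0.5 * h * h * (Fa[i, dd] * invM - gm * vel[i, dd])
                     + sm * h32 * (0.5 * x1 + inv2s3 * x2))
                xi[i, dd] = x1
                Cb[i, dd] = C
                pos[i, dd] += h * vel[i, dd] + C
            # transverse periodic wrap (free monomers only)
            pos[i, 1] -= Lpr * math.floor(pos[i, 1] / Lpr)
            pos[i, 2] -= Lpr * math.floor(pos[i, 2] / Lpr)
        if wall_mobile:
            x1 = rng_thermo.standard_normal()
            x2 = rng_thermo.standard_normal()
            Cw = (0.5 * h * h * (Fw * invMw - gw * Ldot)
                  + sw * h32 * (0.5 * x1 + inv2s3 * x2))
            xiw = x1
            L += h * Ldot + Cw

        # ---- force recomputation
        res = _forces(pos, Fb, rank, fil, jn, Nf, free_list, icounts[0], L, kp)
        if res[6] != 0:
            status = NOT_FINITE
            break
        eU_bond, eU_bend, eU_wf, eU_wm, eF_bun, eF_m = res[:6]
        Fw_new = eF_bun + eF_m - kp.kappa_T * L - kp.pA

        # ---- velocity update (closing half)
        for n in range(1, Nf + 1):
            for k in range(2, jn[n]):
                i = fil[n, k]
                for dd in range(3):
                    vel[i, dd] += (0.5 * h * (Fa[i, dd] + Fb[i, dd]) * invM
                                   - h * gm * vel[i, dd]
                                   + sm * sh * xi[i, dd]
                                   - gm * Cb[i, dd])
        for a in range(nf0):
            i = free_list[a]
            for dd in range(3):
                vel[i, dd] += (0.5 * h * (Fa[i, dd] + Fb[i, dd]) * invM
                               - h * gm * vel[i, dd]
                               + sm * sh * xi[i, dd]
                               - gm * Cb[i, dd])
        if wall_mobile:
            Ldot += (0.5 * h * (Fw + Fw_new) * invMw - h * gw * Ldot
                     + sw * sh * xiw - gw * Cw)
        Fa, Fb = Fb, Fa
        Fw = Fw_new

        t += h
        step += 1

        # ---- Poisson-clocked events at the step boundary -------------------
        while True:
            # reactions scanned first: on a tie they precede reservoir moves
            best = -1
            tbest = t + 1.0
            if chemistry:
                for q in range(1, 2 * Nf + 1):
                    if evt[q] < tbest:
                        tbest = evt[q]
                        best = q
            if reservoir and evt[0] < tbest:
                tbest = evt[0]
                best = 0
            if best < 0 or tbest > t:
                break
            if best == 0:
                # ---- grand-canonical exchange
                evt[0] = tbest + rng_gc.exponential(1.0 / kp.nu_GC)
                V = kp.A * L
                if rng_gc.random() < 0.5:
                    gcc[0] += 1  # insertion attempt
                    x = rng_gc.random() * L
                    y = rng_gc.random() * kp.Lprime
                    z = rng_gc.random() * kp.Lprime
                    if _is_reactive(pos, fil, jn, Nf, x, y, z, kp.r_c, kp.Lprime):
                        gcc[2] += 1
                    elif x > 0.0:
                        dU = (_wall_energy(x, kp.d, kp.eps_w, kp.s_c)
                              + _wall_energy(L - x, kp.d, kp.eps_w, kp.s_c))
                        acc = kp.rho1 * V * math.exp(-kp.beta * dU) / (icounts[0] + 1)
                        if rng_gc.random() < acc:
                            if icounts[1] == 0:
                                status = SLOTS_FULL
                                break
                            icounts[1] -= 1
                            i = slot_stack[icounts[1]]
                            pos[i, 0] = x
                            pos[i, 1] = y
                            pos[i, 2] = z
                            sv = math.sqrt(kp.kBT * invM)
                            vel[i, 0] = sv * rng_gc.standard_normal()
                            vel[i, 1] = sv * rng_gc.standard_normal()
                            vel[i, 2] = sv * rng_gc.standard_normal()
                            Fa[i, 0] = Fa[i, 1] = Fa[i, 2] = 0.0
                            owner[i] = 0
                            rank[i] = 0
                            free_list[icounts[0]] = i
                            free_pos[i] = icounts[0]
                            icounts[0] += 1
                            gcc[1] += 1
                            res = _forces(pos, Fa, rank, fil, jn, Nf,
                                          free_list, icounts[0], L, kp)
                            eU_bond, eU_bend, eU_wf, eU_wm, eF_bun, eF_m = res[:6]
                            Fw = eF_bun + eF_m - kp.kappa_T * L - kp.pA
                else:
                    gcc[3] += 1  # deletion attempt
                    n1 = icounts[0]
                    if n1 > 0:
                        a = int(rng_gc.random() * n1)
                        if a == n1:
                            a = n1 - 1
                        i = free_list[a]
                        if _is_reactive(pos, fil, jn, Nf,
                                        pos[i, 0], pos[i, 1], pos[i, 2],
                                        kp.r_c, kp.Lprime):
                            gcc[5] += 1
                        else:
                            dU = (_wall_energy(pos[i, 0], kp.d, kp.eps_w, kp.s_c)
                                  + _wall_energy(L - pos[i, 0], kp.d, kp.eps_w, kp.s_c))
                            acc = n1 * math.exp(kp.beta * dU) / (kp.rho1 * V)
                            if rng_gc.random() < acc:
                                last = free_list[n1 - 1]
                                free_list[a] = last
                                free_pos[last] = a
                                icounts[0] = n1 - 1
                                owner[i] = -1
                                slot_stack[icounts[1]] = i
                                icounts[1] += 1
                                gcc[4] += 1
                                res = _forces(pos, Fa, rank, fil, jn, Nf,
                                              free_list, icounts[0], L, kp)
                                eU_bond, eU_bend, eU_wf, eU_wm, eF_bun, eF_m = res[:6]
                                Fw = eF_bun + eF_m - kp.kappa_T * L - kp.pA
                    else:
                        gcc[6] += 1  # nothing to delete: counted as refused
            elif best <= Nf:
                # ---- polymerization attempt on filament n = best
                n = best
                evt[best] = tbest + rng_react.exponential(1.0 / kp.nu)
                jnn = jn[n]
                zn = 1 + int(math.floor((L - hn[n]) / kp.d))
                m = jnn - zn
                mi = min(max(m + M_OFFSET, 0), M_SIZE - 1)
                attU[mi] += 1
                it = fil[n, jnn - 1]
                tx, ty, tz = pos[it, 0], pos[it, 1], pos[it, 2]
                # reservoir-sample a uniform candidate within r_c of the tip
                cnt = 0
                sel = -1
                sx = sy = sz = 0.0
                rc = kp.r_c
                rc2 = rc * rc
                for a in range(icounts[0]):
                    i = free_list[a]
                    dx = pos[i, 0] - tx
                    if dx > rc or dx < -rc:
                        continue
                    dy = _min_image(pos[i, 1] - ty, kp.Lprime)
                    if dy > rc or dy < -rc:
                        continue
                    dz = _min_image(pos[i, 2] - tz, kp.Lprime)
                    if dx * dx + dy * dy + dz * dz <= rc2:
                        cnt += 1
                        if rng_react.random() * cnt < 1.0:
                            sel = i
                            sx = tx + dx
                            sy = ty + dy
                            sz = tz + dz
                accepted = 0
                el = 0.0
                if cnt > 0 and jnn < jcap:
                    el, _r = _tip_elastic(pos, fil, n, jnn, sx, sy, sz, kp)
                    acc = cnt * math.exp(-kp.beta * el)
                    if rng_react.random() < acc:
                        # capture: candidate becomes the new tip, in place
                        pos[sel, 0] = sx
                        pos[sel, 1] = sy
                        pos[sel, 2] = sz
                        a = free_pos[sel]
                        last = free_list[icounts[0] - 1]
                        free_list[a] = last
                        free_pos[last] = a
                        icounts[0] -= 1
                        owner[sel] = n
                        rank[sel] = jnn + 1
                        fil[n, jnn] = sel
                        jn[n] = jnn + 1
                        sucU[mi] += 1
                        accepted = 1
                        res = _forces(pos, Fa, rank, fil, jn, Nf,
                                      free_list, icounts[0], L, kp)
                        eU_bond, eU_bend, eU_wf, eU_wm, eF_bun, eF_m = res[:6]
                        Fw = eF_bun + eF_m - kp.kappa_T * L - kp.pA
                elif jnn >= jcap:
                    status = JCAP_FULL
                    break
                if log_level == 2 or (log_level == 1 and accepted == 1):
                    _log_event(ev, icounts, tbest, n, 1, m,
                               -kp.eps0 + el, cnt, accepted)
                if accepted and j_stop > 0 and jn[n] >= j_stop:
                    status = J_STOP
                    break
            else:
                # ---- depolymerization attempt on filament n = best - Nf
                n = best - Nf
                evt[best] = tbest + rng_react.exponential(1.0 / kp.nu)
                jnn = jn[n]
                zn = 1 + int(math.floor((L - hn[n]) / kp.d))
                m = jnn - zn
                mi = min(max(m + M_OFFSET, 0), M_SIZE - 1)
                attW[mi] += 1
                accepted = 0
                el = 0.0
                if jnn > 2:
                    u = rng_react.random()
                    # acc <= exp(-beta eps0): cheap early rejection
                    if u < exp_eps0:
                        it = fil[n, jnn - 1]
                        ip = fil[n, jnn - 2]
                        dx = pos[it, 0] - pos[ip, 0]
                        dy = pos[it, 1] - pos[ip, 1]
                        dz = pos[it, 2] - pos[ip, 2]
                        r = math.sqrt(dx * dx + dy * dy + dz * dz)
                        el = 0.5 * kp.ks * (r - kp.d) ** 2
                        if jnn >= 4:
                            ip2 = fil[n, jnn - 3]
                            b1x = pos[ip, 0] - pos[ip2, 0]
                            b1y = pos[ip, 1] - pos[ip2, 1]
                            b1z = pos[ip, 2] - pos[ip2, 2]
                        else:
                            # triple (1,2,3): seed bond along +x
                            b1x, b1y, b1z = kp.d, 0.0, 0.0
                        n1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
                        c = (b1x * dx + b1y * dy + b1z * dz) / (n1 * r)
                        el += kp.kappa * (1.0 - c)
                        if r <= kp.r_c:  # reverse-move reachability guard
                            ipn = fil[n, jnn - 2]
                            nr = 1 + _count_candidates(
                                pos, free_list, icounts[0],
                                pos[ipn, 0], pos[ipn, 1], pos[ipn, 2],
                                kp.r_c, kp.Lprime, -1)
                            ratio = math.exp(kp.beta * el) / nr
                            acc = exp_eps0 * (ratio if ratio < 1.0 else 1.0)
                            if u < acc:
                                # release: tip becomes a free monomer in place
                                jn[n] = jnn - 1
                                owner[it] = 0
                                rank[it] = 0
                                pos[it, 1] -= kp.Lprime * math.floor(
                                    pos[it, 1] / kp.Lprime)
                                pos[it, 2] -= kp.Lprime * math.floor(
                                    pos[it, 2] / kp.Lprime)
                                free_list[icounts[0]] = it
                                free_pos[it] = icounts[0]
                                icounts[0] += 1
                                sucW[mi] += 1
                                accepted = 1
                                res = _forces(pos, Fa, rank, fil, jn, Nf,
                                              free_list, icounts[0], L, kp)
                                eU_bond, eU_bend, eU_wf, eU_wm, eF_bun, eF_m = res[:6]
                                Fw = eF_bun + eF_m - kp.kappa_T * L - kp.pA
                if log_level == 2 or (log_level == 1 and accepted == 1):
                    _log_event(ev, icounts, tbest, n, -1, m,
                               kp.eps0 - el, -1, accepted)
        if status != OK:
            break

        # ---- per-step residence counters
        for n in range(1, Nf + 1):
            m = jn[n] - (1 + int(math.floor((L - hn[n]) / kp.d)))
            Q[min(max(m + M_OFFSET, 0), M_SIZE - 1)] += 1

        # ---- trace recording
        if stride > 0 and step % stride == 0:
            row = icounts[2]
            if row >= tr_t.shape[0]:
                status = TRACE_FULL
                break
            tr_t[row] = t
            tr_L[row] = L
            tr_Ldot[row] = Ldot
            tr_N1[row] = icounts[0]
            for n in range(1, Nf + 1):
                it = fil[n, jn[n] - 1]
                i0 = fil[n, 0]
                tr_j[row, n - 1] = jn[n]
                tr_X[row, n - 1] = pos[it, 0] - pos[i0, 0]
                dyt = pos[it, 1] - pos[i0, 1]
                dzt = pos[it, 2] - pos[i0, 2]
                tr_R[row, n - 1] = math.sqrt(dyt * dyt + dzt * dzt)
            tr_E[row, 0] = eU_bond
            tr_E[row, 1] = eU_bend
            tr_E[row, 2] = eU_wf
            tr_E[row, 3] = eU_wm
            tr_E[row, 4] = eF_bun
            tr_E[row, 5] = eF_m
            icounts[2] = row + 1

        if not (math.isfinite(L) and math.isfinite(Ldot)
                and math.isfinite(eU_bond + eU_bend + eU_wf + eU_wm)):
            status = NOT_FINITE
            break

    return status, step, L, Ldot, t
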