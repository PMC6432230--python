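"""Equilibrium and kinetic observables: wall distribution, m-resolved
rates, autocorrelation functions and the summary report.

The wall influence on the chemistry is resolved by the relative size
``m = i_n - z_n``, where ``z_n = 1 + floor((L - h_n)/d)`` is the largest
size a filament seeded at ``h_n`` can have without touching the wall at
``L``; ``m >= 0`` flags a filament pressing on the wall.  Effective
rates are residence-time-weighted: the success counter at each m is
divided by the residence counter at that m and by the time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .params import SimulationParams
from .state import Counters
from .theory import hill_theory

__all__ = [
    "crossover_index", "relative_index", "rates_table", "wall_histogram",
    "gaussian_wall_reference", "autocorrelation", "fit_exponentials",
    "block_error", "qm_slope", "equilibrium_summary",
]


def crossover_index(L, h_n, d: float = 1.0):
    """Largest non-wall-touching filament size ``z_n = 1 + floor((L - h_n)/d)``."""
    L = np.asarray(L, dtype=float)
    h_n = np.asarray(h_n, dtype=float)
    if np.any(L <= h_n):
        raise ValueError("wall position must exceed the seed offset")
    return (1 + np.floor((L - h_n) / d)).astype(int)


def relative_index(i_n, z_n):
    """Filament size relative to the crossover index; m > 0 hits the wall."""
    return np.asarray(i_n, dtype=int) - np.asarray(z_n, dtype=int)


def rates_table(counters: Counters, h: float, Nf: int = 1,
                min_residence: int = 1) -> pd.DataFrame:
    """m-resolved residence weights and attempt/effective rates [1/tauD].

    ``Q`` is normalized to unit sum over m.  Rates at an m with fewer
    than ``min_residence`` residence counts are reported as NaN.
    """
    c = counters
    ms = np.arange(len(c.Q)) - c.m_offset
    sel = (c.Q > 0) | (c.attU > 0) | (c.attW > 0)
    ms = ms[sel]
    Q = c.Q[sel].astype(float)
    # residence time at m per filament-step counter: Q counts are
    # (filament, step) pairs, so residence time = Q * h
    res_t = Q * h
    with np.errstate(divide="ignore", invalid="ignore"):
        Um = np.where(Q >= min_residence, c.sucU[sel] / res_t, np.nan)
        Wm = np.where(Q >= min_residence, c.sucW[sel] / res_t, np.nan)
        Um_att = np.where(Q >= min_residence, c.attU[sel] / res_t, np.nan)
        Wm_att = np.where(Q >= min_residence, c.attW[sel] / res_t, np.nan)
    return pd.DataFrame({
        "m": ms,
        "Q": Q / Q.sum(),
        "residence_time": res_t,
        "U_att": Um_att, "W_att": Wm_att,
        "U": Um, "W": Wm,
        "n_U": c.sucU[sel], "n_W": c.sucW[sel],
    })


def plateau_rates(table: pd.DataFrame, m_max_W: int = -1, m_max_U: int = -2,
                  min_events: int = 1):
    """Bulk plateau rates ``(U0, W0)`` from the m-resolved table.

    Residence-time-weighted averages of the effective rates over the
    plateau region (m <= -2 for polymerization, m <= -1 for
    depolymerization), where the wall no longer interferes.
    """
    tW = table[(table.m <= m_max_W) & table.W.notna()]
    tU = table[(table.m <= m_max_U) & table.U.notna()]
    W0 = tW.n_W.sum() / tW.residence_time.sum() if len(tW) else float("nan")
    U0 = tU.n_U.sum() / tU.residence_time.sum() if len(tU) else float("nan")
    nW = int(tW.n_W.sum()) if len(tW) else 0
    nU = int(tU.n_U.sum()) if len(tU) else 0
    if nW < min_events or nU < min_events:
        raise ValueError("too few plateau events for a rate estimate")
    return U0, W0, nU, nW


def qm_slope(table: pd.DataFrame, m_min: int = -10, m_max: int = -1):
    """Fitted slope of ln<Q_m> over the exponential-rise region.

    Returns ``(rho_hat_fit, slope, stderr)``: at equilibrium
    ``Q_{m+1}/Q_m = rho_hat1`` below wall contact, so the slope of
    ln Q_m against m estimates ln rho_hat1.
    """
    t = table[(table.m >= m_min) & (table.m <= m_max) & (table.Q > 0)]
    if len(t) < 3:
        raise ValueError("fewer than 3 populated m bins in the fit window")
    x = t.m.to_numpy(dtype=float)
    y = np.log(t.Q.to_numpy())
    w = np.sqrt(t.Q.to_numpy() * t.residence_time.sum())  # ~1/rel. error
    coef, cov = np.polyfit(x, y, 1, w=w, cov=True)
    slope = coef[0]
    return math.exp(slope), slope, math.sqrt(cov[0, 0])


def wall_histogram(L_series, bin_width: float = 0.1):
    """Normalized histogram of the wall position.

    Returns ``(centers, density)``; the default 0.1 d bin resolves the
    monomer-scale oscillations a single filament imprints on P(L).
    """
    L = np.asarray(L_series, dtype=float)
    if L.size == 0:
        raise ValueError("empty wall-position series")
    lo = math.floor(L.min() / bin_width) * bin_width
    hi = math.ceil(L.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    dens, edges = np.histogram(L, bins=edges, density=True)
    return 0.5 * (edges[1:] + edges[:-1]), dens


def gaussian_wall_reference(L_grid, Nf: int, kappa_T: float, rho_hat1: float,
                            d: float = 1.0, kBT: float = 1.0):
    """Mean-field P(L) for rigid filaments: Gaussian at L_H, width sigma_H.

    Follows from the bundle free energy Omega(L) = -F_H L combined with
    the trap energy kappa_T L^2 / 2.
    """
    _, L_H, sigma_H = hill_theory(Nf, kappa_T, rho_hat1, d, kBT)
    L_grid = np.asarray(L_grid, dtype=float)
    return (np.exp(-0.5 * ((L_grid - L_H) / sigma_H) ** 2)
            / (sigma_H * math.sqrt(2.0 * math.pi)))


def autocorrelation(series, max_lag: int | None = None):
    """Unbiased autocovariance of the fluctuations, by FFT.

    ``acf[k] = <dA(t) dA(t + k)>`` with ``dA = A - <A>``; ``acf[0]`` is
    the series variance.
    """
    a = np.asarray(series, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("series too short for an autocorrelation")
    da = a - a.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    fa = np.fft.rfft(da, nfft)
    acov = np.fft.irfft(fa * np.conj(fa), nfft)[:n]
    acov /= np.arange(n, 0, -1)  # unbiased normalization
    if max_lag is not None:
        acov = acov[:max_lag + 1]
    return acov


def fit_exponentials(lags, acf, n_components: int = 1):
    """Least-squares fit of an ACF by one or two decaying exponentials.

    Returns ``(amplitudes, times)`` sorted by decreasing time.  The fit
    window is iterated once: a log-linear regression on the positive
    initial decay provides a first time estimate, then the fit spans
    lags up to three times that estimate.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    lags = np.asarray(lags, dtype=float)
    acf = np.asarray(acf, dtype=float)
    if acf[0] <= 0:
        raise RuntimeError("ACF has non-positive variance; cannot fit")
    pos = acf > 0.05 * acf[0]
    if pos.sum() < 4:
        raise RuntimeError("ACF decays immediately: relaxation is not "
                           "resolved at this sampling stride")
    # initial estimate from the log-linear decay
    n0 = np.argmin(pos) if not pos.all() else len(acf)
    k = max(4, n0 // 2)
    slope = np.polyfit(lags[:k], np.log(acf[:k]), 1)[0]
    tau0 = -1.0 / slope if slope < 0 else lags[-1]

    for _ in range(2):
        win = lags <= 3.0 * tau0
        if win.sum() < 3 * n_components:
            win = np.ones_like(lags, dtype=bool)
        x, y = lags[win], acf[win]
        if n_components == 1:
            f = lambda tt, a, tau: a * np.exp(-tt / tau)
            p0 = [acf[0], tau0]
        else:
            f = lambda tt, a1, t1, a2, t2: (a1 * np.exp(-tt / t1)
                                            + a2 * np.exp(-tt / t2))
            p0 = [0.5 * acf[0], tau0, 0.5 * acf[0], tau0 / 10.0]
        try:
            popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise RuntimeError(f"exponential ACF fit failed: {exc}") from exc
        taus = np.abs(popt[1::2])
        tau0 = float(taus.max())
    amps = popt[0::2]
    order = np.argsort(taus)[::-1]
    return amps[order], taus[order]


def block_error(series, n_blocks: int = 10) -> float:
    """Standard error of the mean by block averaging."""
    a = np.asarray(series, dtype=float)
    if a.size < 2 * n_blocks:
        return float("nan")
    usable = a[: (a.size // n_blocks) * n_blocks]
    means = usable.reshape(n_blocks, -1).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_blocks))


@dataclass
class EquilibriumSummary:
    table: pd.DataFrame       # property, mean, std, stderr
    rates: pd.DataFrame       # m-resolved table
    rho_hat_fit: float
    rho_hat_fit_err: float
    warnings: list

    def __str__(self) -> str:
        lines = [self.table.to_string(index=False),
                 f"Qm slope fit: rho_hat1 = {self.rho_hat_fit:.4g}"]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


def equilibrium_summary(trace, counters: Counters,
                        params: SimulationParams,
                        n_blocks: int = 10) -> EquilibriumSummary:
    """Equilibrium averages, fluctuations and consistency checks.

    Reports the trap length, bundle/filament sizes, end-to-end
    components, free-monomer count and wall forces with block-averaged
    standard errors, plus the fitted slope of ln<Q_m>.  Drift between
    the two halves of the trace beyond 3 combined standard errors is
    flagged as an equilibration warning.
    """
    warnings = []
    rows = []

    def add(name, series, per_filament=False):
        s = np.asarray(series, dtype=float)
        if per_filament:
            mean, std = s.mean(), s.std()
            se = block_error(s.mean(axis=1) if s.ndim == 2 else s, n_blocks)
        else:
            mean, std = s.mean(), (s.std() if s.size > 1 else float("nan"))
            se = block_error(s, n_blocks)
        rows.append((name, mean, std, se))
        return mean, se

    L_mean, L_se = add("L", trace.L)
    add("I", trace.I)
    add("i", trace.j, per_filament=True)
    add("X", trace.X, per_filament=True)
    add("R_perp", trace.R_perp, per_filament=True)
    add("N1", trace.N1)
    F_bun_mean, _ = add("F_bun", trace.E[:, 4])
    add("F_bun_sq", trace.E[:, 4] ** 2)
    F_m_mean, _ = add("F_w_m", trace.E[:, 5])
    rows.append(("kT_L", params.kappa_T * L_mean, float("nan"), float("nan")))

    # stationarity of the wall equation of motion:
    # kappa_T <L> = <F_bun> + <F_w_m> - pA
    balance = F_bun_mean + F_m_mean - params.pA - params.kappa_T * L_mean
    rows.append(("force_balance_residual", balance, float("nan"), float("nan")))

    half = len(trace.L) // 2
    if half > 4:
        m1, m2 = trace.L[:half].mean(), trace.L[half:].mean()
        se_h = math.hypot(block_error(trace.L[:half], max(2, n_blocks // 2)),
                          block_error(trace.L[half:], max(2, n_blocks // 2)))
        if se_h > 0 and abs(m1 - m2) > 3 * se_h:
            warnings.append(
                f"possible drift: half-trace means {m1:.3f} vs {m2:.3f} "
                f"differ by more than 3 SE ({se_h:.3f})")

    rates = rates_table(counters, params.h, params.Nf)
    try:
        rho_fit, _, rho_err = qm_slope(rates)
    except ValueError as exc:
        rho_fit, rho_err = float("nan"), float("nan")
        warnings.append(str(exc))

    table = pd.DataFrame(rows, columns=["property", "mean", "std", "stderr"])
    return EquilibriumSummary(table, rates, rho_fit, rho_err, warnings)
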