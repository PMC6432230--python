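import math

import numpy as np
import pandas as pd
import pytest

import filatrap as ft
from filatrap.state import Counters
from filatrap.observables import (crossover_index, relative_index,
                                  rates_table, plateau_rates, qm_slope,
                                  wall_histogram, gaussian_wall_reference,
                                  autocorrelation, fit_exponentials,
                                  block_error, equilibrium_summary)
from filatrap.simulation import Trace
from filatrap.theory import hill_theory, brownian_ratchet_velocity


class TestRelativeIndex:
    def test_simple_crossover(self):
        assert crossover_index(47.0, 0.0) == 48
        assert relative_index(48, 48) == 0

    def test_staggered_offset_crossover(self):
        # L = 26.5, h = 0.4375: floor(26.0625) = 26 -> z = 27, i=26 -> m=-1
        z = crossover_index(26.5, 0.4375)
        assert z == 27
        assert relative_index(26, z) == -1

    def test_vectorized_over_filaments(self):
        z = crossover_index(26.5, np.array([0.0, 0.4375]))
        assert list(z) == [27, 27]

    def test_wall_below_seed_rejected(self):
        with pytest.raises(ValueError):
            crossover_index(0.2, 0.4375)


class TestRateEstimators:
    def test_residence_only_gives_zero_rates(self, params):
        c = Counters()
        c.Q[c.m_offset - 3] = 1000
        t = rates_table(c, params.h)
        assert len(t) == 1
        assert t.iloc[0].m == -3 and t.iloc[0].Q == 1.0
        assert t.iloc[0].U == 0.0 and t.iloc[0].W == 0.0

    def test_single_event_rate_is_inverse_residence(self, params):
        # one depolymerization at m=-2 over residence time Theta: W = 1/Theta
        c = Counters()
        steps = 5000
        c.Q[c.m_offset - 2] = steps
        c.attW[c.m_offset - 2] = 7
        c.sucW[c.m_offset - 2] = 1
        t = rates_table(c, params.h)
        theta = steps * params.h
        assert t.iloc[0].W == pytest.approx(1.0 / theta)
        assert t.iloc[0].W_att == pytest.approx(7.0 / theta)

    def test_hand_computed_toy_log(self, params):
        # 20 events spread over three m bins, exact arithmetic
        c = Counters()
        spec = {-2: (10000, 8, 3), -1: (30000, 24, 12), 0: (20000, 10, 5)}
        for m, (q, att, suc) in spec.items():
            c.Q[c.m_offset + m] = q
            c.attU[c.m_offset + m] = att
            c.sucU[c.m_offset + m] = suc
        t = rates_table(c, params.h).set_index("m")
        for m, (q, att, suc) in spec.items():
            assert t.loc[m, "U"] == pytest.approx(suc / (q * params.h))
        assert t.Q.sum() == pytest.approx(1.0)

    def test_qm_slope_recovers_geometric_ratio(self, params):
        c = Counters()
        for m in range(-8, 1):
            c.Q[c.m_offset + m] = int(1e6 * 2.5 ** m)
        rho, slope, err = qm_slope(rates_table(c, params.h))
        assert rho == pytest.approx(2.5, rel=1e-3)


class TestWallHistogram:
    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wall_histogram([])

    def test_histogram_is_normalized_density(self, rng):
        L = rng.normal(47.3, 7.2, 20000)
        centers, dens = wall_histogram(L, bin_width=0.1)
        assert np.sum(dens) * 0.1 == pytest.approx(1.0, rel=1e-6)

    def test_gaussian_reference_peaks_at_hill_length(self):
        grid = np.linspace(20, 35, 2001)
        ref = gaussian_wall_reference(grid, 8, 0.275, 2.5)
        assert grid[np.argmax(ref)] == pytest.approx(26.66, abs=0.01)


class TestAutocorrelation:
    def _ou(self, tau, n, dt, rng, sigma=1.0):
        x = np.empty(n)
        x[0] = rng.normal(0, sigma)
        a = math.exp(-dt / tau)
        b = sigma * math.sqrt(1 - a * a)
        for k in range(1, n):
            x[k] = a * x[k - 1] + b * rng.normal()
        return x

    def test_zero_lag_is_variance(self, rng):
        x = rng.normal(2.0, 3.0, 4000)
        acf = autocorrelation(x)
        assert acf[0] == pytest.approx(x.var(), rel=1e-10)

    def test_recovers_ou_relaxation_time(self, rng):
        tau, dt = 20.0, 0.5
        x = self._ou(tau, int(120 * tau / dt), dt, rng)
        acf = autocorrelation(x, max_lag=int(8 * tau / dt))
        lags = np.arange(len(acf)) * dt
        amps, taus = fit_exponentials(lags, acf, 1)
        assert taus[0] == pytest.approx(tau, rel=0.10)
        assert amps[0] == pytest.approx(x.var(), rel=0.2)

    def test_recovers_two_component_mixture(self, rng):
        t1, t2, dt = 50.0, 4.0, 0.5
        n = int(150 * t1 / dt)
        x = self._ou(t1, n, dt, rng) + self._ou(t2, n, dt, rng, sigma=0.8)
        acf = autocorrelation(x, max_lag=int(6 * t1 / dt))
        lags = np.arange(len(acf)) * dt
        amps, taus = fit_exponentials(lags, acf, 2)
        assert taus[0] == pytest.approx(t1, rel=0.25)
        assert taus[1] == pytest.approx(t2, rel=0.5)

    def test_white_noise_is_flagged_degenerate(self, rng):
        x = rng.normal(0, 1, 5000)
        acf = autocorrelation(x, max_lag=100)
        with pytest.raises(RuntimeError, match="decays immediately"):
            fit_exponentials(np.arange(101.0), acf, 1)


class TestTheoryReferences:
    def test_hill_single_filament(self):
        F, L, s = hill_theory(1, 0.019375, 2.5)
        assert L == pytest.approx(47.3, abs=0.05)

    def test_hill_bundle(self):
        F, L, s = hill_theory(8, 0.275, 2.5)
        assert L == pytest.approx(26.6, abs=0.06)
        assert s == pytest.approx(1.9069, abs=1e-4)

    def test_critical_density_exerts_no_force(self):
        F, L, s = hill_theory(4, 0.1, 1.0)
        assert F == 0.0 and L == 0.0

    def test_ratchet_velocity_limits(self):
        assert brownian_ratchet_velocity(0.0, 0.203, 0.080) == pytest.approx(0.123)
        stall = math.log(0.203 / 0.080)
        assert brownian_ratchet_velocity(stall, 0.203, 0.080) == pytest.approx(
            0.0, abs=1e-12)


class TestEquilibriumSummary:
    def _synthetic_trace(self, params, n=4000, rng=None):
        rng = rng or np.random.default_rng(4)
        L = rng.normal(47.3, 1.0, n)
        j = rng.poisson(46, (n, 1))
        E = np.zeros((n, 6))
        # wall balance satisfied on average:
        # F_bun = kappa_T L + pA - F_w_m with F_w_m ~ pA
        E[:, 5] = params.pA + rng.normal(0, 0.05, n)
        E[:, 4] = params.kappa_T * L + params.pA - E[:, 5]
        return Trace(t=np.arange(n) * 0.1, L=L, Ldot=np.zeros(n),
                     N1=rng.poisson(105, n), j=j, X=j - 1.2 + 0.0,
                     R_perp=np.abs(rng.normal(3, 1, (n, 1))), E=E)

    def test_force_balance_residual_vanishes(self, params):
        tr = self._synthetic_trace(params)
        c = Counters()
        c.Q[c.m_offset - 3:c.m_offset] = [16, 40, 100]
        s = equilibrium_summary(tr, c, params)
        row = s.table.set_index("property")
        assert abs(row.loc["force_balance_residual", "mean"]) < 0.01
        assert row.loc["kT_L", "mean"] == pytest.approx(
            params.kappa_T * row.loc["L", "mean"])

    def test_degenerate_single_sample(self, params):
        tr = self._synthetic_trace(params, n=1)
        s = equilibrium_summary(tr, Counters(), params)
        assert math.isnan(s.table.set_index("property").loc["L", "stderr"])

    def test_drift_warning_on_nonstationary_trace(self, params):
        tr = self._synthetic_trace(params)
        tr.L[:] = np.linspace(30, 60, len(tr.L))  # blatant drift
        s = equilibrium_summary(tr, Counters(), params)
        assert any("drift" in w for w in s.warnings)


def test_block_error_matches_iid_scaling(rng):
    x = rng.normal(0, 2.0, 10000)
    se = block_error(x, 10)
    assert se == pytest.approx(2.0 / math.sqrt(10000), rel=0.6)
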