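import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import filatrap as ft
from filatrap.energetics import (bond_energy, bend_energy, wall_energy,
                                 wall_force_mag, bulk_equilibrium_constant,
                                 compute_forces)
from filatrap.state import build_initial_state


class TestBondEnergy:
    def test_rest_length_gives_minus_eps0(self, params):
        assert bond_energy(1.0, params) == pytest.approx(-13.644143)

    def test_stretched_bond(self, params):
        # ks/2 * 0.1^2 = 20 on top of -eps0
        assert bond_energy(1.1, params) == pytest.approx(-13.644143 + 20.0)

    @given(delta=st.floats(1e-6, 0.5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_even_about_rest_length(self, delta):
        p = ft.SimulationParams()
        assert bond_energy(1.0 + delta, p) == pytest.approx(
            bond_energy(1.0 - delta, p))


class TestBendEnergy:
    def test_straight_is_zero(self, params):
        assert bend_energy(0.0, params) == 0.0

    def test_right_angle_is_kappa(self, params):
        assert bend_energy(math.pi / 2, params) == pytest.approx(5370.0)

    @pytest.mark.parametrize("theta", [0.01, 0.05, 0.1])
    def test_harmonic_limit(self, theta, params):
        assert bend_energy(theta, params) == pytest.approx(
            0.5 * params.kappa_bend * theta ** 2, rel=0.01)


class TestWallEnergy:
    def test_zero_at_and_beyond_cutoff(self, params):
        assert wall_energy(params.s_c, params) == pytest.approx(0.0, abs=1e-14)
        assert wall_energy(2.0, params) == 0.0

    def test_value_at_one_monomer_size(self, params):
        # the 9-3 bracket vanishes at s = d, leaving eps_w
        assert wall_energy(1.0, params) == pytest.approx(0.1)

    def test_strictly_decreasing_inside_cutoff(self, params):
        s = np.linspace(0.4, params.s_c, 300)
        u = wall_energy(s, params)
        assert np.all(np.diff(u) < 0)

    def test_effective_core_where_energy_is_kBT(self, params):
        # Uw(s*) = kBT at s* = 3^(-1/6) d ~ 0.8327 d for eps_w = 0.1
        s_star = brentq(lambda s: float(wall_energy(s, params)) - 1.0, 0.5, 1.1)
        assert s_star == pytest.approx(3.0 ** (-1 / 6), rel=1e-6)

    def test_crossed_wall_is_an_error(self, params):
        with pytest.raises(ValueError, match="crossed"):
            wall_energy(-0.1, params)

    @given(s=st.floats(0.4, 1.11))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_force_is_minus_gradient(self, s):
        p = ft.SimulationParams()
        eps = 1e-7
        num = -(wall_energy(s + eps, p) - wall_energy(s - eps, p)) / (2 * eps)
        assert wall_force_mag(s, p) == pytest.approx(float(num), rel=1e-5)


class TestBulkEquilibriumConstant:
    def test_printed_values(self, params):
        K0, rho1c, mu1c = bulk_equilibrium_constant(params)
        assert K0 == pytest.approx(39.07144, rel=1e-4)
        assert rho1c == pytest.approx(0.025594, rel=1e-4)
        assert mu1c == pytest.approx(-3.6654, abs=2e-4)

    def test_stiff_limit_bracket(self, params):
        # Lp -> infinity: the [1 - exp(-2 Lp/d)] bracket saturates at 1,
        # so K0 * Lp approaches a constant
        p1 = params.replace(kappa_bend=1e6)
        p2 = params.replace(kappa_bend=2e6)
        k1 = bulk_equilibrium_constant(p1)[0] * p1.Lp
        k2 = bulk_equilibrium_constant(p2)[0] * p2.Lp
        assert k1 == pytest.approx(k2, rel=1e-8)


class TestForces:
    def _straight_state(self, params, j):
        state = build_initial_state(params, 40.0, j_init=j, jcap=j + 5)
        from filatrap.protocols import strip_free_monomers
        strip_free_monomers(state)
        return state

    def test_straight_relaxed_filament_has_zero_force(self, params):
        state = self._straight_state(params, 5)
        F, fw, br = compute_forces(state, params)
        mobile = state.fil[1, 2:state.jn[1]]
        assert np.abs(F[mobile]).max() < 1e-10
        assert br.U_bond == pytest.approx(-3 * params.eps0)
        assert br.U_bend == pytest.approx(0.0, abs=1e-12)

    def test_monomer_at_distance_d_from_mobile_wall(self, params):
        # |dUw/ds| at s = d is eps_w * (3 sqrt3/2) * 6 / d = 1.5588 kBT/d
        state = self._straight_state(params, 5)
        i = state.fil[1, 4]
        state.pos[i, 0] = state.L - 1.0
        # detach: make it free so only wall forces act on it
        state.jn[1] = 4
        state.owner[i] = 0
        state.free_list[0] = i
        state.free_pos[i] = 0
        state.icounts[0] = 1
        F, fw, br = compute_forces(state, params)
        expected = 0.1 * (3 * math.sqrt(3) / 2) * 6
        assert F[i, 0] == pytest.approx(-expected)
        assert br.F_w_m == pytest.approx(expected)

    def test_wall_force_without_contacts_is_trap_plus_gas(self, params):
        state = self._straight_state(params, 3)
        _, fw, br = compute_forces(state, params)
        assert br.F_w_bun == 0.0 and br.F_w_m == 0.0
        assert fw == pytest.approx(-params.kappa_T * state.L - params.pA)

    def test_force_is_minus_gradient_of_energy(self, params, rng):
        # randomized bent/stretched filament + free monomers near walls
        state = build_initial_state(
            params.replace(seed=77), 12.0, j_init=6, jcap=12)
        mobile = list(state.fil[1, 2:state.jn[1]])
        mobile += list(state.free_list[:state.N1])
        for i in mobile:
            state.pos[i] += rng.normal(0.0, 0.01, 3)
        F, fw, br = compute_forces(state, params)

        def total_U(st):
            _, _, b = compute_forces(st, params)
            return b.total_potential

        eps = 1e-6
        for i in mobile[:6]:
            for dd in range(3):
                state.pos[i, dd] += eps
                up = total_U(state)
                state.pos[i, dd] -= 2 * eps
                um = total_U(state)
                state.pos[i, dd] += eps
                num = -(up - um) / (2 * eps)
                assert F[i, dd] == pytest.approx(num, rel=2e-5, abs=1e-7)

    def test_wall_force_is_minus_dU_dL(self, params):
        # move the wall by delta: energy changes by -F_monomeric * delta
        state = build_initial_state(params.replace(seed=5), 10.0,
                                    j_init=9, jcap=14)
        _, _, br0 = compute_forces(state, params)
        fmono = br0.F_w_bun + br0.F_w_m
        eps = 1e-6
        state.L += eps
        _, _, bp = compute_forces(state, params)
        state.L -= 2 * eps
        _, _, bm = compute_forces(state, params)
        state.L += eps
        num = -(bp.total_potential - bm.total_potential) / (2 * eps)
        assert fmono == pytest.approx(num, rel=1e-5, abs=1e-8)
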