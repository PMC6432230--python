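import math

import numpy as np
import pytest

import filatrap as ft
from filatrap.simulation import Simulation
from filatrap.state import build_initial_state
from filatrap.protocols import strip_free_monomers
from filatrap.reactions import (is_reactive, candidate_count, poly_acceptance,
                                depoly_acceptance, tip_elastic_energy)


@pytest.fixture
def state_with_probe(params):
    """j=4 filament plus one free monomer we can place at will."""
    st = build_initial_state(params, 30.0, j_init=4, jcap=10)
    strip_free_monomers(st)
    i = st.slot_stack[st.icounts[1] - 1]
    st.icounts[1] -= 1
    st.owner[i] = 0
    st.free_list[0] = i
    st.free_pos[i] = 0
    st.icounts[0] = 1
    return st, i


class TestReactiveRegion:
    def test_just_inside_sphere(self, params, state_with_probe):
        st, i = state_with_probe
        tip = st.fil[1, st.jn[1] - 1]
        st.pos[i] = st.pos[tip] + [0.99 * params.r_c, 0.0, 0.0]
        assert is_reactive(st, i)
        assert candidate_count(st, 1) == 1

    def test_just_outside_sphere(self, params, state_with_probe):
        st, i = state_with_probe
        tip = st.fil[1, st.jn[1] - 1]
        st.pos[i] = st.pos[tip] + [1.01 * params.r_c, 0.0, 0.0]
        assert not is_reactive(st, i)
        assert candidate_count(st, 1) == 0

    def test_periodic_image_counts(self, params, state_with_probe):
        # candidate just across the transverse boundary is still in range
        st, i = state_with_probe
        tip = st.fil[1, st.jn[1] - 1]
        st.pos[i] = st.pos[tip] + [0.0, params.L_prime - 0.5, 0.0]
        st.pos[i, 1] %= params.L_prime
        assert is_reactive(st, i)

    def test_filament_monomer_rejected(self, params, state_with_probe):
        st, _ = state_with_probe
        with pytest.raises(ValueError, match="not a free monomer"):
            is_reactive(st, int(st.fil[1, 2]))


class TestAcceptanceRules:
    def test_ideal_straight_candidate_always_accepted(self, params,
                                                      state_with_probe):
        st, i = state_with_probe
        tip = st.fil[1, st.jn[1] - 1]
        point = st.pos[tip] + [1.0, 0.0, 0.0]
        el = tip_elastic_energy(st, 1, point)
        assert el == pytest.approx(0.0, abs=1e-12)
        assert poly_acceptance(params, 1, el) == 1.0

    def test_no_candidate_means_rejection(self, params):
        assert poly_acceptance(params, 0, 0.0) == 0.0

    def test_release_probability_is_bond_energy_scale(self, params):
        # perfect bond, single candidate after release: exp(-beta eps0)
        assert depoly_acceptance(params, 1, 0.0) == pytest.approx(
            1.1876e-6, rel=1e-3)
        assert depoly_acceptance(params, 1, 0.0) == pytest.approx(
            math.exp(-13.644143))

    def test_pair_satisfies_detailed_balance_pointwise(self, params):
        # acceptance ratio must equal N_r exp(-beta dU), dU = -eps0 + el
        for el in (0.0, 0.5, 2.0, 14.0):
            for n_r in (1, 2, 5):
                ratio = (poly_acceptance(params, n_r, el)
                         / depoly_acceptance(params, n_r, el))
                expected = n_r * math.exp(params.beta * (params.eps0 - el))
                assert ratio == pytest.approx(expected, rel=1e-12)

    def test_stretched_candidate_strongly_suppressed(self, params,
                                                     state_with_probe):
        st, i = state_with_probe
        tip = st.fil[1, st.jn[1] - 1]
        el = tip_elastic_energy(st, 1, st.pos[tip] + [1.3, 0.0, 0.0])
        assert el == pytest.approx(0.5 * params.ks * 0.09)  # 180 kBT
        assert poly_acceptance(params, 3, el) < 1e-70


class TestSeedProtection:
    def test_bare_seed_never_depolymerizes(self, params):
        st = build_initial_state(params.replace(seed=8), 15.0, j_init=2)
        strip_free_monomers(st)
        sim = Simulation(params.replace(seed=8), state=st)
        sim.run(1.0, wall_mobile=False, reservoir=False, check=False)
        assert sim.state.jn[1] == 2
        assert sim.counters.attW.sum() > 0       # clocks fired
        assert sim.counters.sucW.sum() == 0      # but never accepted


class TestBulkSegments:
    def test_segment_restarts_accumulate_plateau_counters(self):
        # far-parked wall, growing filament: segments restart at j_stop
        # and pool their counters; the depolymerization plateau sits at
        # the nu*exp(-beta eps0) scale
        from filatrap.protocols import bulk_chemistry_run
        res = bulk_chemistry_run(seed=800, duration=150.0, j_start=5,
                                 j_stop=7, L_box=25.0)
        assert res["segments"] >= 1
        assert res["n_depoly"] >= 1
        assert 0.0 < res["W0"] < 1.0
        table = res["table"]
        assert (table.m < -10).all()  # tip never near the wall


class TestReactionEventLog:
    def test_successful_events_logged_with_topology_change(self, params):
        p = params.replace(seed=12)
        sim = Simulation(p, L0=20.0)
        j0 = int(sim.state.jn[1])
        sim.run(30.0, wall_mobile=False, log_level=1, check=True)
        ev = sim.event_dataframe()
        if len(ev):  # growth from a bare seed is slow but steady
            assert set(ev.direction.unique()) <= {1, -1}
            assert (ev.accepted == 1).all()
            net = int((ev.direction == 1).sum() - (ev.direction == -1).sum())
            assert int(sim.state.jn[1]) == j0 + net
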