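"""Carbon economy: respiration, allocation, alternate bearing, soil pools."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olivecan import carbon as cb
from olivecan.carbon import (
    C_CH2O,
    GrowthParams,
    SoilCarbonParams,
    SoilCarbonState,
    TreeCarbonState,
    allocate_growth,
    daily_assimilate_pool,
    determine_fruit_number,
    distribute_fine_root_growth,
    ecosystem_fluxes,
    frost_defoliation,
    maintenance_respiration,
    senescence_turnover,
    shoots_to_branches,
    soil_carbon_step,
)

G = GrowthParams()


class FakeStep:
    def __init__(self, temp, dt):
        self.temp = temp
        self.dt = dt


def make_state(**kw):
    defaults = dict(
        leaves=300.0,
        shoot_cohorts=np.array([30.0, 25.0, 20.0]),
        branches=900.0,
        coarse_roots=450.0,
        fine_roots=np.full((2, 4), 10.0),
        fruits=100.0,
        reserves=50.0,
    )
    defaults.update(kw)
    return TreeCarbonState(**defaults)


class TestMaintenanceRespiration:
    def test_zero_biomass(self):
        empty = TreeCarbonState(fine_roots=np.zeros((2, 4)),
                                shoot_cohorts=np.zeros(3))
        assert maintenance_respiration(empty, [FakeStep(25, 1.0)], G) == 0.0

    def test_q10_law(self):
        state = make_state()
        base = maintenance_respiration(state, [FakeStep(20.0, 1.0)], G)
        warm = maintenance_respiration(state, [FakeStep(30.0, 1.0)], G)
        assert warm == pytest.approx(G.q10 * base, rel=1e-12)

    def test_double_sum_oracle(self):
        state = make_state()
        temps = [12.0, 18.0, 26.0, 31.0]
        steps = [FakeStep(t, 0.25) for t in temps]
        got = maintenance_respiration(state, steps, G)
        expected = 0.0
        for organ, biomass in state.organ_biomass().items():
            for t in temps:
                expected += G.km(organ) * biomass * G.q10 ** ((t - 20.0) / 10.0) * 0.25
        assert got == pytest.approx(expected, rel=1e-12)


class TestAssimilatePool:
    def test_deficit_drawn_from_reserves(self):
        pool, reserves, _, starving = daily_assimilate_pool(
            2.0, 0.0, 10.0, 5.0, G
        )
        assert pool == 0.0
        assert reserves == pytest.approx(10.0 - 3.0)
        assert not starving

    def test_starvation_floor(self):
        pool, reserves, _, starving = daily_assimilate_pool(1.0, 0.0, 1.0, 5.0, G)
        assert pool == 0.0 and reserves == 0.0 and starving

    def test_remobilization_min_rule(self):
        # demand exceeds supply: remobilized = min(f_remob * reserves, gap)
        pool, reserves, _, _ = daily_assimilate_pool(
            4.0, 0.0, 100.0, 1.0, G, demand=20.0
        )
        assert pool == pytest.approx(3.0 + G.f_remob * 100.0)
        assert reserves == pytest.approx(100.0 * (1 - G.f_remob))
        pool2, reserves2, _, _ = daily_assimilate_pool(
            4.0, 0.0, 1000.0, 1.0, G, demand=3.5
        )
        assert pool2 == pytest.approx(3.5)
        assert reserves2 == pytest.approx(1000.0 - 0.5)

    def test_fruit_photosynthesis_credited(self):
        pool, _, fp, _ = daily_assimilate_pool(5.0, 200.0, 0.0, 1.0, G,
                                               fruit_active=True)
        assert fp == pytest.approx(G.fruit_photo_coef * 200.0)
        assert pool == pytest.approx(4.0 + fp)


class TestFruitNumber:
    def test_total_heat_kill(self):
        p = dataclasses.replace(G, heat_fn_reduction=1.0)
        assert determine_fruit_number(100.0, 500.0, 1, p) == 0.0

    def test_on_year_after_off_year(self):
        fn_off = determine_fruit_number(800.0, 500.0, 0, G)
        fn_on = determine_fruit_number(0.0, 500.0, 0, G)
        assert fn_on == pytest.approx(G.fn_per_node * 500.0)
        assert fn_on > fn_off

    @given(st.floats(0, 2000), st.floats(0, 2000), st.integers(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_recurrence_oracle(self, fn_prev, nodes, hot):
        got = determine_fruit_number(fn_prev, nodes, hot, G)
        expected = max(0.0, G.fn_per_node * nodes - G.fn_feedback * fn_prev)
        expected *= (1 - G.heat_fn_reduction) ** hot
        assert got == pytest.approx(expected, rel=1e-12)


class TestAllocation:
    def test_empty_pool(self):
        growth, resp_g, surplus, spent = allocate_growth(0.0, 500.0, 8.0, True, True, G)
        assert all(v == 0.0 for v in growth.values())
        assert resp_g == 0.0 and surplus == 0.0 and spent == 0.0

    def test_sink_limited_fruits_get_exactly_demand(self):
        fn, dtt = 100.0, 5.0
        demand_dm = fn * G.fruit_pot_rate * dtt
        growth, _, _, _ = allocate_growth(1000.0, fn, dtt, True, True, G)
        assert growth["fruits"] == pytest.approx(demand_dm, rel=1e-12)

    def test_source_limited_fruits_get_whole_pool(self):
        fn, dtt = 5000.0, 12.0
        pool = 0.5
        growth, _, surplus, spent = allocate_growth(pool, fn, dtt, False, True, G)
        assert growth["fruits"] == pytest.approx(pool * G.pv_fruits)
        assert surplus == pytest.approx(0.0)

    def test_dormant_season_pool_goes_to_reserves(self):
        growth, resp_g, surplus, _ = allocate_growth(7.0, 0.0, 0.0, False, False, G)
        assert surplus == pytest.approx(7.0)
        assert all(v == 0.0 for v in growth.values())

    @given(
        st.floats(0.0, 50.0),
        st.floats(0.0, 3000.0),
        st.floats(0.0, 15.0),
        st.booleans(),
        st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_substrate_conservation(self, pool, fn, dtt, active, fruiting):
        growth, resp_g, surplus, spent = allocate_growth(
            pool, fn, dtt, active, fruiting, G
        )
        substrate = sum(
            growth[o] / G.pv(o) for o in growth if growth[o] > 0
        )
        assert substrate + surplus == pytest.approx(pool, abs=1e-9)
        assert spent == pytest.approx(substrate, abs=1e-9)
        assert resp_g >= -1e-12


class TestTurnoverAndCohorts:
    def test_zero_rate_no_change(self):
        p = dataclasses.replace(G, leaf_turnover=0.0, fine_root_turnover=0.0)
        state = make_state()
        new, leaf_l, root_l = senescence_turnover(state, p)
        assert leaf_l == 0.0 and root_l == 0.0
        assert new.leaves == state.leaves

    def test_exponential_decay_oracle(self):
        lam = 0.01
        p = dataclasses.replace(G, leaf_turnover=lam, fine_root_turnover=0.0)
        state = make_state()
        b0 = state.leaves
        for _ in range(30):
            state, _, _ = senescence_turnover(state, p)
        assert state.leaves == pytest.approx(b0 * (1 - lam) ** 30, rel=1e-9)

    def test_litter_equals_loss(self):
        state = make_state()
        new, leaf_l, root_l = senescence_turnover(state, G)
        assert leaf_l == pytest.approx(state.leaves - new.leaves)
        assert root_l == pytest.approx(
            state.fine_roots_total - new.fine_roots_total
        )

    def test_cohort_queue_over_three_years(self):
        state = make_state(shoot_cohorts=np.array([10.0, 7.0, 4.0]), branches=0.0)
        queue = [10.0, 7.0, 4.0]
        branches = 0.0
        for _ in range(3):
            state = shoots_to_branches(state)
            branches += queue.pop()
            queue.insert(0, 0.0)
            np.testing.assert_allclose(state.shoot_cohorts, queue)
            assert state.branches == pytest.approx(branches)

    def test_woody_total_conserved(self):
        state = make_state()
        before = state.shoots + state.branches
        after = shoots_to_branches(state)
        assert after.shoots + after.branches == pytest.approx(before)


class TestFrost:
    def test_above_onset_no_damage(self):
        state = make_state()
        new, litter = frost_defoliation(-5.0, state, G)
        assert litter == 0.0 and new.leaves == state.leaves

    def test_midpoint_half_defoliation(self):
        state = make_state()
        mid = 0.5 * (G.frost_t_onset + G.frost_t_full)
        new, litter = frost_defoliation(mid, state, G)
        assert litter == pytest.approx(0.5 * state.leaves)

    @pytest.mark.parametrize("tmin", np.linspace(-20, 5, 11))
    def test_piecewise_linear_sweep(self, tmin):
        state = make_state()
        _, litter = frost_defoliation(tmin, state, G)
        if tmin >= G.frost_t_onset:
            expected = 0.0
        else:
            expected = min(
                (G.frost_t_onset - tmin) / (G.frost_t_onset - G.frost_t_full), 1.0
            ) * state.leaves
        assert litter == pytest.approx(expected)


class TestFineRootDistribution:
    def test_all_growth_to_wet_layer(self):
        inc = distribute_fine_root_growth(
            5.0, [1.0], [0.5, 0.5],
            theta=[[0.07, 0.23]], theta_ul=[[0.23, 0.23]], theta_ll=[[0.07, 0.07]],
        )
        assert inc[0, 0] == 0.0
        assert inc[0, 1] == pytest.approx(5.0)

    def test_uniform_conditions_split_equally(self):
        inc = distribute_fine_root_growth(
            8.0, [0.5, 0.5], [0.5, 0.5],
            theta=np.full((2, 2), 0.15), theta_ul=np.full((2, 2), 0.23),
            theta_ll=np.full((2, 2), 0.07),
        )
        np.testing.assert_allclose(inc, 2.0)

    @given(st.floats(0.0, 20.0), st.integers(0, 10))
    @settings(max_examples=30, deadline=None)
    def test_conservation(self, total, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0.05, 0.35, (2, 4))
        inc = distribute_fine_root_growth(
            total, [0.85, 0.15], [0.3, 0.5, 0.6, 0.6],
            theta=theta, theta_ul=np.full((2, 4), 0.23),
            theta_ll=np.full((2, 4), 0.07),
        )
        assert inc.sum() == pytest.approx(total, abs=1e-9)

    def test_bone_dry_profile_falls_back_to_volume(self):
        inc = distribute_fine_root_growth(
            6.0, [0.5, 0.5], [1.0, 2.0],
            theta=np.full((2, 2), 0.05), theta_ul=np.full((2, 2), 0.23),
            theta_ll=np.full((2, 2), 0.07),
        )
        assert inc.sum() == pytest.approx(6.0)
        assert inc[0, 1] == pytest.approx(2.0 * inc[0, 0])


class TestSoilCarbon:
    P = SoilCarbonParams()

    def test_empty_pools_silent(self):
        resp, pools = soil_carbon_step(
            SoilCarbonState(0.0, 0.0), 0.0, 0.0, 20.0, 0.5, self.P
        )
        assert resp == 0.0

    def test_first_order_decay_oracle(self):
        pools = SoilCarbonState(fresh=100.0, humus=0.0)
        rate = self.P.k_fresh * self.P.q10 ** 0.0 * cb.soil_moisture_modifier(0.5)
        for _ in range(20):
            _, pools = soil_carbon_step(pools, 0.0, 0.0, 20.0, 0.5, self.P)
        assert pools.fresh == pytest.approx(100.0 * (1 - rate) ** 20, rel=1e-9)

    @given(st.floats(0, 10), st.floats(0, 10), st.floats(-5, 40), st.floats(0, 1.5))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, litter, residue, temp, theta_rel):
        pools = SoilCarbonState(fresh=120.0, humus=3000.0)
        resp, new = soil_carbon_step(pools, litter, residue, temp, theta_rel, self.P)
        lhs = litter + residue
        rhs = (new.fresh - pools.fresh) + (new.humus - pools.humus) + resp
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestEcosystemFluxes:
    def test_identities_and_signs(self):
        f = ecosystem_fluxes(10.0, 0.5, 3.0, 1.0, 2.0)
        assert f.resp_eco == pytest.approx(6.0)
        assert f.nee == pytest.approx(6.0 - 10.5)
        dark = ecosystem_fluxes(0.0, 0.0, 3.0, 1.0, 2.0)
        assert dark.nee > 0  # pure respiration day: carbon source
        balanced = ecosystem_fluxes(6.0, 0.0, 3.0, 1.0, 2.0)
        assert balanced.nee == pytest.approx(0.0)
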