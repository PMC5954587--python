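"""Soil water balance: interception, runoff, drainage, evaporation, closure."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olivecan import soil_water as sw


def make_layers(theta=0.18, n=4, lv=0.5):
    return [
        sw.SoilLayerState(dz=0.5, theta=theta, theta_ul=0.23, theta_ll=0.07,
                          theta_sat=0.40, lv=lv)
        for _ in range(n)
    ]


def make_zone(theta=0.18, fraction=1.0, cn=75.0, **kw):
    return sw.SoilZoneState(fraction=fraction, layers=make_layers(theta), cn=cn, **kw)


class TestInterception:
    def test_bare_canopy_intercepts_nothing(self):
        p_eff, store = sw.intercept_rainfall(10.0, sw.CanopyWaterStore(), lai=0.0)
        assert p_eff == 10.0 and store.stored == 0.0

    def test_no_rain_no_change(self):
        s0 = sw.CanopyWaterStore(stored=0.3, capacity=0.8)
        p_eff, store = sw.intercept_rainfall(0.0, s0, lai=2.0)
        assert p_eff == 0.0 and store.stored == pytest.approx(0.3)

    def test_min_rule(self):
        # capacity = 0.4 * 2 = 0.8 mm, empty store: P_int = min(10, 0.8)
        p_eff, store = sw.intercept_rainfall(
            10.0, sw.CanopyWaterStore(), lai=2.0, c_int=0.4
        )
        assert store.stored == pytest.approx(0.8)
        assert p_eff == pytest.approx(10.0 - 0.8)

    def test_negative_rain_rejected(self):
        with pytest.raises(ValueError):
            sw.intercept_rainfall(-1.0, sw.CanopyWaterStore(), lai=1.0)


class TestWetCanopyEvaporation:
    def test_empty_store(self):
        ecan, store, blocked = sw.evaporate_intercepted(
            sw.CanopyWaterStore(0.0, 1.0), 15.0, 25.0, 2.0, 2.0, 4.0
        )
        assert ecan == 0.0 and not blocked

    def test_exhaustion(self):
        ecan, store, blocked = sw.evaporate_intercepted(
            sw.CanopyWaterStore(0.05, 1.0), 20.0, 30.0, 3.0, 3.0, 4.0
        )
        assert ecan == pytest.approx(0.05)
        assert store.stored == pytest.approx(0.0, abs=1e-12)
        assert not blocked

    def test_matches_independent_penman_monteith(self):
        """Null-resistance PM recomputed from its textbook form."""
        rn, t, vpd, u, h = 12.0, 28.0, 2.5, 2.0, 4.0
        ecan, _, _ = sw.evaporate_intercepted(
            sw.CanopyWaterStore(50.0, 60.0), rn, t, vpd, u, h
        )
        es = 0.6108 * math.exp(17.27 * t / (t + 237.3))
        delta = 4098.0 * es / (t + 237.3) ** 2
        d, z0m = 0.65 * h, 0.1 * h
        ra = (
            math.log((10.0 - d) / z0m)
            * math.log((10.0 - d) / (0.01 * h))
            / (0.41**2 * u)
        )
        expected = (
            delta * rn + 86400 * 1.013e-3 * 1.225 * vpd / ra
        ) / (delta + 0.0665) / 2.45
        assert ecan == pytest.approx(expected, rel=1e-12)


class TestRunoff:
    def test_zero_depth(self):
        assert sw.curve_number_runoff(0.0, 75.0) == 0.0

    def test_impervious_limit(self):
        assert sw.curve_number_runoff(30.0, 100.0) == pytest.approx(30.0)

    def test_closed_form(self):
        s = 25400.0 / 75.0 - 254.0
        expected = (50.0 - 0.2 * s) ** 2 / (50.0 + 0.8 * s)
        assert sw.curve_number_runoff(50.0, 75.0) == pytest.approx(expected)

    @given(
        st.floats(0.0, 200.0), st.floats(0.0, 200.0), st.floats(30.0, 99.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonic_in_depth_and_cn(self, d1, d2, cn):
        lo, hi = sorted([d1, d2])
        assert sw.curve_number_runoff(hi, cn) >= sw.curve_number_runoff(lo, cn)
        assert sw.curve_number_runoff(hi, min(cn + 5, 100)) >= sw.curve_number_runoff(
            hi, cn
        )

    def test_cn_out_of_range(self):
        with pytest.raises(ValueError):
            sw.curve_number_runoff(10.0, 0.0)

    def test_partition_conserves_volume(self):
        fr = [0.85, 0.15]
        depths = sw.partition_effective_precip(8.0, fr)
        assert depths == [8.0, 8.0]
        assert sum(f * d for f, d in zip(fr, depths)) == pytest.approx(8.0)

    def test_partition_requires_unit_fractions(self):
        with pytest.raises(ValueError):
            sw.partition_effective_precip(5.0, [0.5, 0.4])


class TestDrainage:
    def test_profile_at_field_capacity_static(self):
        layers = make_layers(theta=0.23)
        out, d = sw.drain_and_redistribute(layers, 0.0)
        assert d == 0.0
        assert all(a.theta == pytest.approx(b.theta) for a, b in zip(layers, out))

    def test_full_swcon_drains_to_field_capacity(self):
        layers = make_layers(theta=0.30)
        out, d = sw.drain_and_redistribute(layers, 0.0, swcon=1.0)
        for layer in out:
            assert layer.theta == pytest.approx(0.23)
        expected = sum((0.30 - 0.23) * l.dz * 1000 for l in layers)
        assert d == pytest.approx(expected)

    @given(
        st.floats(0.07, 0.38),
        st.floats(0.0, 80.0),
        st.floats(0.0, 30.0),
        st.floats(0.05, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_conservation(self, theta, infil, irr, swcon):
        layers = make_layers(theta=theta)
        before = sum(l.water_mm for l in layers)
        out, d = sw.drain_and_redistribute(layers, infil, irr, swcon=swcon)
        after = sum(l.water_mm for l in out)
        assert after + d == pytest.approx(before + infil + irr, abs=1e-9)
        assert all(0 <= l.theta <= l.theta_sat for l in out)

    def test_no_drainage_below_field_capacity(self):
        layers = make_layers(theta=0.15)
        _, d = sw.drain_and_redistribute(layers, 0.0)
        assert d == 0.0


class TestSoilEvaporation:
    def test_stage1_equals_potential_times_shading(self):
        zone = make_zone(theta=0.22)
        es, _ = sw.soil_evaporation(zone, es_potential=5.0, soil_rad_fraction=0.6)
        assert es == pytest.approx(5.0 * 0.6)

    def test_saturated_calm_air_near_zero(self):
        zone = make_zone(theta=0.22)
        es, _ = sw.soil_evaporation(zone, es_potential=0.0, soil_rad_fraction=0.6)
        assert es == pytest.approx(0.0)

    def test_stage2_sqrt_time_ratio(self):
        alpha = 3.5
        zone = make_zone(theta=0.22, cum_stage1=9.0, t_stage2=0)
        rates = []
        for _ in range(4):
            es, zone = sw.soil_evaporation(
                zone, es_potential=10.0, soil_rad_fraction=1.0, alpha_stage2=alpha
            )
            rates.append(es)
        assert rates[0] == pytest.approx(alpha * 1.0)
        assert rates[3] == pytest.approx(alpha * (math.sqrt(4) - math.sqrt(3)))
        assert rates[3] / rates[0] == pytest.approx(math.sqrt(4) - math.sqrt(3))

    def test_wetted_zone_microadvection_exceeds_dry(self):
        dry = make_zone(theta=0.22)
        wet = make_zone(theta=0.22, fraction=1.0)
        es_d, _ = sw.soil_evaporation(dry, 4.0, 0.6, microadvection=1.0)
        es_w, _ = sw.soil_evaporation(wet, 4.0, 0.6, microadvection=1.3)
        assert es_w > es_d

    def test_never_below_air_dry(self):
        zone = make_zone(theta=0.04)
        es, out = sw.soil_evaporation(
            zone, es_potential=10.0, soil_rad_fraction=1.0, airdry_fraction=0.5
        )
        for layer in out.layers[:2]:
            assert layer.theta >= 0.5 * layer.theta_ll - 1e-12


class TestZoneStep:
    def test_quiescent_day_all_zero(self):
        zone = make_zone(theta=0.23)
        fluxes, _ = sw.zone_water_step(zone, 0.0, 0.0, 0.0, 0.0)
        for f in ("p_eff", "runoff", "drainage", "es", "rwu", "irrigation"):
            assert getattr(fluxes, f) == pytest.approx(0.0)

    def test_irrigation_reaches_only_the_wetted_zone(self):
        """Irrigating the wetted zone must leave a dry-zone step untouched."""
        dry = make_zone(theta=0.15, fraction=0.85)
        fluxes_a, dry_a = sw.zone_water_step(dry, 0.0, 0.0, 2.0, 0.5)
        fluxes_b, dry_b = sw.zone_water_step(dry, 0.0, 0.0, 2.0, 0.5)
        wet = make_zone(theta=0.15, fraction=0.15)
        sw.zone_water_step(wet, 0.0, 20.0, 2.0, 0.5)  # irrigation elsewhere
        for la, lb in zip(dry_a.layers, dry_b.layers):
            assert la.theta == lb.theta

    def test_hundred_day_cumulative_closure(self):
        rng = np.random.default_rng(4)
        zone = make_zone(theta=0.20)
        total_in = total_out = 0.0
        start = zone.water_mm
        for _ in range(100):
            rain = float(rng.gamma(0.8, 6.0)) if rng.random() < 0.3 else 0.0
            irr = float(rng.uniform(0, 6)) if rng.random() < 0.2 else 0.0
            fluxes, zone = sw.zone_water_step(
                zone, rain, irr, float(rng.uniform(0, 6)), 0.6
            )
            total_in += fluxes.p_eff + fluxes.irrigation
            total_out += fluxes.runoff + fluxes.drainage + fluxes.es + fluxes.rwu
        resid = (total_in - total_out) - (zone.water_mm - start)
        assert abs(resid) < 0.01

    def test_closure_invariant_enforced(self):
        fl = sw.ZoneWaterFluxes(
            p_eff=5.0, runoff=1.0, infiltration=4.0, drainage=0.0,
            es=1.0, rwu=0.0, irrigation=0.0, delta_storage=1.0,
        )
        with pytest.raises(sw.WaterBalanceError):
            fl.check_closure()


class TestAntecedentCn:
    def test_three_classes(self):
        cn2 = 75.0
        cn_dry = sw.adjust_cn_for_moisture(cn2, 0.1)
        cn_avg = sw.adjust_cn_for_moisture(cn2, 0.5)
        cn_wet = sw.adjust_cn_for_moisture(cn2, 0.9)
        assert cn_avg == pytest.approx(cn2)
        assert cn_dry < cn2 < cn_wet
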