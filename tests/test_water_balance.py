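"""Layered water bucket: runoff, drainage, evaporation, supply/demand."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorgsim.errors import StateError
from sorgsim.soil import SoilLayer, SoilProfile
from sorgsim import water_balance as wb


def make_profile(n=2, dul=0.30, cll=0.10, sw=0.30, thick=15.0, kl=0.08):
    layers, top = [], 0.0
    for _ in range(n):
        layers.append(SoilLayer(top, top + thick, 1.2, dul=dul, cll=cll, sw=sw, kl=kl))
        top += thick
    return SoilProfile(layers, "synthetic")


class TestRainPartition:
    def test_no_rain_no_fluxes(self, two_layer_profile):
        state = wb.WaterState()
        assert wb.partition_rain(0.0, state, two_layer_profile) == (0.0, 0.0)

    def test_small_rain_below_initial_abstraction_all_infiltrates(self):
        # CN 80 -> S = 63.5 mm, 0.2 S = 12.7 mm threshold
        state = wb.WaterState()
        runoff, infil = wb.partition_rain(5.0, state, make_profile(sw=0.15))
        assert runoff == 0.0
        assert infil == pytest.approx(5.0)

    def test_large_storm_runoff_matches_curve_number_formula(self):
        state = wb.WaterState()
        runoff, infil = wb.partition_rain(50.0, state, make_profile(n=6, sw=0.15))
        s = 25400 / 80 - 254
        assert runoff == pytest.approx((50 - 0.2 * s) ** 2 / (50 + 0.8 * s))
        assert runoff == pytest.approx(13.8, abs=0.05)
        assert infil == pytest.approx(50 - runoff)

    def test_infiltration_fills_top_down_and_spills_below(self):
        prof = make_profile(n=2, sw=0.30)  # both layers already at dul
        state = wb.WaterState()
        wb.partition_rain(60.0, state, prof)
        # layers can only hold dul + 0.05 saturation each = 7.5 mm per layer
        assert prof.layers[0].sw == pytest.approx(prof.layers[0].saturation)
        assert state.cum_drainage > 0  # surplus left the profile


class TestDrainage:
    def test_no_drainage_at_dul(self):
        prof = make_profile(sw=0.30)
        assert wb.drain(wb.WaterState(), prof) == 0.0

    def test_single_layer_sheds_swcon_fraction(self):
        prof = SoilProfile([SoilLayer(0, 100, 1.2, dul=0.30, cll=0.10, sw=0.31)])
        # 10 mm above dul; 30% drains, 7 mm retained above dul
        out = wb.drain(wb.WaterState(), prof, swcon=0.3)
        assert out == pytest.approx(3.0)
        assert (prof.layers[0].sw - 0.30) * 1000 == pytest.approx(7.0)

    def test_repeated_drainage_converges_geometrically(self):
        prof = SoilProfile([SoilLayer(0, 100, 1.2, dul=0.30, cll=0.10, sw=0.31)])
        excess = [10.0]
        for _ in range(5):
            wb.drain(wb.WaterState(), prof, swcon=0.3)
            excess.append((prof.layers[0].sw - 0.30) * 1000)
        ratios = [b / a for a, b in zip(excess, excess[1:])]
        assert ratios == pytest.approx([0.7] * 5, rel=1e-9)


class TestSoilEvaporation:
    def test_full_cover_suppresses_evaporation(self):
        prof = make_profile()
        es = wb.soil_evaporation(wb.WaterState(), prof, 20, 30, 15, cover=1.0)
        assert es == 0.0

    def test_air_dry_top_layer_yields_nothing(self):
        prof = make_profile(sw=0.05)  # clamped to air-dry = 0.5 * cll
        es = wb.soil_evaporation(wb.WaterState(), prof, 20, 30, 15, cover=0.0)
        assert es == 0.0

    def test_stage_one_is_bounded_by_u(self):
        prof = make_profile()
        state = wb.WaterState()  # freshly wetted
        first = wb.soil_evaporation(state, prof, 25, 35, 18, cover=0.0)
        assert first <= 6.0 + 1e-9  # stage 1 never exceeds U in total
        assert state.es_since_wetting <= 6.0 + 1e-9

    def test_stage_two_declines_with_sqrt_time(self):
        prof = make_profile(sw=0.30)
        state = wb.WaterState(es_since_wetting=6.0)  # stage 1 exhausted
        es = [wb.soil_evaporation(state, prof, 25, 35, 18, cover=0.0) for _ in range(4)]
        assert all(b < a for a, b in zip(es, es[1:]))
        assert es[0] == pytest.approx(3.5 * (math.sqrt(1) - 0))


class TestVpd:
    def test_zero_at_equal_extremes(self):
        assert wb.vpd_estimate(20, 20) == 0.0

    def test_matches_svp_formula(self):
        svp = lambda t: 0.6106 * math.exp(17.27 * t / (t + 237.3))
        assert wb.vpd_estimate(30, 15) == pytest.approx(0.75 * (svp(30) - svp(15)))
        assert wb.vpd_estimate(30, 15) == pytest.approx(1.90, abs=0.01)

    def test_monotone_in_tmax(self):
        vals = [wb.vpd_estimate(tmax, 15) for tmax in (20, 25, 30, 35)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSupplyDemand:
    def test_dry_profile_gives_zero_supply_and_full_stress(self):
        prof = make_profile(sw=0.10)  # at cll
        roots = wb.RootZone(depth=30.0)
        supply, demand, sd = wb.supply_and_demand(prof, roots, 20.0, 2.0)
        assert supply == 0.0
        assert demand > 0
        assert sd == 0.0

    def test_no_demand_means_no_stress(self):
        prof = make_profile()
        supply, demand, sd = wb.supply_and_demand(prof, wb.RootZone(depth=30.0), 0.0, 2.0)
        assert demand == 0.0
        assert sd == 1.0

    def test_demand_follows_transpiration_efficiency_units(self):
        # te 9 Pa at vpd 2 kPa -> TE = 4.5 g m^-2 mm^-1 -> 20 g needs 4.44 mm
        prof = make_profile()
        _, demand, _ = wb.supply_and_demand(prof, wb.RootZone(depth=30.0), 20.0, 2.0)
        assert demand == pytest.approx(20.0 / 4.5, abs=1e-6)

    def test_supply_prorated_by_root_penetration(self):
        prof = make_profile(n=2)
        full = wb.supply_and_demand(prof, wb.RootZone(depth=30.0), 10.0, 2.0)[0]
        half = wb.supply_and_demand(prof, wb.RootZone(depth=22.5), 10.0, 2.0)[0]
        assert half == pytest.approx(0.75 * full)

    def test_sd_ratio_monotone_in_stored_water(self):
        roots = wb.RootZone(depth=30.0)
        sds = []
        for sw in (0.12, 0.16, 0.20, 0.24):
            sd = wb.supply_and_demand(make_profile(sw=sw), roots, 30.0, 2.0)[2]
            sds.append(sd)
        assert all(b >= a for a, b in zip(sds, sds[1:]))
        assert all(0 <= v <= 1 for v in sds)


class TestExtraction:
    def test_zero_extraction_changes_nothing(self):
        prof = make_profile()
        before = [l.sw for l in prof.layers]
        wb.extract_transpiration(wb.WaterState(), prof, wb.RootZone(depth=30.0), 0.0)
        assert [l.sw for l in prof.layers] == before

    def test_identical_layers_split_evenly(self):
        prof = make_profile(n=2)
        taken = wb.extract_transpiration(
            wb.WaterState(), prof, wb.RootZone(depth=30.0), 4.0
        )
        assert taken == pytest.approx([2.0, 2.0])

    def test_unequal_layers_split_proportionally_to_kl_weighted_water(self):
        layers = [
            SoilLayer(0, 15, 1.2, dul=0.30, cll=0.10, sw=0.30, kl=0.08),
            SoilLayer(15, 30, 1.2, dul=0.30, cll=0.10, sw=0.20, kl=0.04),
        ]
        prof = SoilProfile(layers)
        weights = [0.08 * 0.20 * 150, 0.04 * 0.10 * 150]  # brute-force oracle
        expected = [3.0 * w / sum(weights) for w in weights]
        taken = wb.extract_transpiration(
            wb.WaterState(), prof, wb.RootZone(depth=30.0), 3.0
        )
        assert taken == pytest.approx(expected, abs=1e-9)
        assert sum(taken) == pytest.approx(3.0, abs=1e-9)

    def test_request_above_supply_is_a_contract_violation(self):
        prof = make_profile()
        with pytest.raises(StateError):
            wb.extract_transpiration(wb.WaterState(), prof, wb.RootZone(depth=30.0), 500.0)

    def test_no_layer_falls_below_cll(self):
        prof = make_profile(n=3)
        roots = wb.RootZone(depth=45.0)
        for _ in range(50):
            supply = wb.supply_and_demand(prof, roots, 100.0, 2.0)[0]
            wb.extract_transpiration(wb.WaterState(), prof, roots, supply * 0.9)
        assert all(l.sw >= l.cll - 1e-12 for l in prof.layers)


class TestDailyClosure:
    @given(
        rain=st.floats(0, 80),
        sw=st.floats(0.06, 0.34),
        growth=st.floats(0, 30),
    )
    @settings(max_examples=150, deadline=None)
    def test_storage_delta_equals_flux_sum(self, rain, sw, growth):
        prof = make_profile(n=3, sw=sw)
        state = wb.WaterState()
        roots = wb.RootZone(depth=40.0)
        stored0 = wb.stored_water_mm(prof)
        _, infil = wb.partition_rain(rain, state, prof)
        spill = state.cum_drainage
        drained = wb.drain(state, prof) + spill
        es = wb.soil_evaporation(state, prof, 22, 33, 18, cover=0.3)
        supply, demand, sd = wb.supply_and_demand(prof, roots, growth, 1.8)
        transp = min(supply, demand)
        wb.extract_transpiration(state, prof, roots, transp)
        stored1 = wb.stored_water_mm(prof)
        assert stored1 - stored0 == pytest.approx(
            infil - drained - es - transp, abs=1e-6
        )
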