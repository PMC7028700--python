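import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soyflood.soil import (
    SAT_EPS,
    SoilLayer,
    SoilProfile,
    SoilWaterState,
    accessible_mineral_n,
    air_filled_porosity_at,
    available_supply,
    force_flood,
    fraction_roots_submerged,
    step_mineral_n,
    step_water_balance,
    take_up_mineral_n,
    water_table_depth,
    wfps_excess_fraction,
)


def _state(profile, sw):
    return SoilWaterState(
        sw=np.asarray(sw, dtype=float), mineral_n=np.zeros(profile.n_layers)
    )


class TestValidation:
    @pytest.mark.parametrize(
        "ll,dul,sat", [(0.3, 0.2, 0.4), (0.2, 0.4, 0.3), (0.2, 0.2, 0.4)]
    )
    def test_hydraulic_ordering_enforced(self, ll, dul, sat):
        with pytest.raises(ValueError):
            SoilLayer(100, ll, dul, sat, 1.4, ks=10.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            SoilProfile(())


class TestWaterBalance:
    def test_no_forcing_is_identity(self, simple_profile, simple_state):
        out = step_water_balance(simple_profile, simple_state, 0.0, 0.0)
        np.testing.assert_allclose(out.sw, simple_state.sw)

    def test_single_layer_fills_pore_space(self):
        prof = SoilProfile((SoilLayer(100, 0.2, 0.3, 0.4, 1.4, ks=0.0),))
        out = step_water_balance(prof, _state(prof, [0.3]), 10.0, 0.0)
        assert out.sw[0] == pytest.approx(0.4)
        assert out.cum_runoff == pytest.approx(0.0)
        assert out.cum_drainage == pytest.approx(0.0)

    def test_excess_beyond_saturation_runs_off(self):
        prof = SoilProfile((SoilLayer(100, 0.2, 0.3, 0.4, 1.4, ks=0.0),))
        out = step_water_balance(prof, _state(prof, [0.3]), 25.0, 0.0)
        assert out.sw[0] == pytest.approx(0.4)
        assert out.cum_runoff == pytest.approx(15.0)

    def test_pond_holds_surface_excess_until_capacity(self):
        prof = SoilProfile(
            (SoilLayer(100, 0.2, 0.3, 0.4, 1.4, ks=0.0),), pond_capacity=8.0
        )
        out = step_water_balance(prof, _state(prof, [0.3]), 25.0, 0.0)
        assert out.pond_mm == pytest.approx(8.0)
        assert out.cum_runoff == pytest.approx(7.0)
        assert water_table_depth(prof, out) == 0.0

    def test_negative_inputs_rejected(self, simple_profile, simple_state):
        with pytest.raises(ValueError):
            step_water_balance(simple_profile, simple_state, -1.0, 0.0)

    @given(
        rain=st.floats(0, 80),
        evap=st.floats(0, 8),
        fracs=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
    )
    def test_conservation_closes(self, rain, evap, fracs):
        prof = SoilProfile(
            (
                SoilLayer(300, 0.20, 0.30, 0.40, 1.4, ks=20.0),
                SoilLayer(300, 0.20, 0.30, 0.40, 1.4, ks=10.0),
                SoilLayer(300, 0.22, 0.32, 0.42, 1.4, ks=5.0),
                SoilLayer(300, 0.22, 0.32, 0.42, 1.4, ks=1.0),
            ),
            pond_capacity=5.0,
        )
        ll, sat = prof.arr("ll15"), prof.arr("sat")
        sw = ll + np.asarray(fracs) * (sat - ll)
        state = _state(prof, sw)
        before = state.stored_water(prof)
        out = step_water_balance(prof, state, rain, evap)
        after = out.stored_water(prof)
        balance = rain - out.cum_runoff - out.cum_drainage - out.cum_evap - (after - before)
        assert balance == pytest.approx(0.0, abs=1e-6)
        assert np.all(out.sw <= sat + 1e-12)
        assert np.all(out.sw >= ll - 1e-12)

    def test_transpiration_precondition_enforced(self, simple_profile, simple_state):
        too_much = np.full(4, 1e4)
        with pytest.raises(ValueError, match="transpiration"):
            step_water_balance(simple_profile, simple_state, 0.0, 0.0, too_much)


class TestWaterTable:
    def test_fully_saturated_is_zero(self, simple_profile):
        st_ = _state(simple_profile, simple_profile.arr("sat"))
        assert water_table_depth(simple_profile, st_) == 0.0

    def test_unsaturated_is_profile_depth(self, simple_profile, simple_state):
        assert water_table_depth(simple_profile, simple_state) == 1200.0

    def test_bottom_two_of_four(self, simple_profile):
        sw = simple_profile.arr("dul").copy()
        sw[2:] = simple_profile.arr("sat")[2:]
        assert water_table_depth(simple_profile, _state(simple_profile, sw)) == 600.0

    def test_perched_block_detected(self, simple_profile):
        sw = simple_profile.arr("dul").copy()
        sw[1] = simple_profile.arr("sat")[1]  # lens at 300-600 over dry subsoil
        assert water_table_depth(simple_profile, _state(simple_profile, sw)) == 300.0


class TestForceFlood:
    def test_water_table_at_surface(self, simple_profile, simple_state):
        out = force_flood(simple_profile, simple_state)
        assert water_table_depth(simple_profile, out) == 0.0

    def test_idempotent_on_saturated(self, simple_profile):
        st_ = _state(simple_profile, simple_profile.arr("sat"))
        out = force_flood(simple_profile, st_)
        assert out.cum_flood_irrigation == pytest.approx(0.0)

    def test_added_water_from_dul(self, simple_profile, simple_state):
        out = force_flood(simple_profile, simple_state)
        expected = float(
            np.sum(
                (simple_profile.arr("sat") - simple_profile.arr("dul"))
                * simple_profile.thickness
            )
        )
        assert out.cum_flood_irrigation == pytest.approx(expected)


class TestDiagnostics:
    def test_fraction_submerged_cases(self):
        assert fraction_roots_submerged(1000.0, 0.0) == 1.0
        assert fraction_roots_submerged(1000.0, 1500.0) == 0.0
        assert fraction_roots_submerged(1000.0, 200.0) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            fraction_roots_submerged(0.0, 100.0)

    def test_wfps_anchors(self, simple_profile):
        at_dul = _state(simple_profile, simple_profile.arr("dul"))
        at_sat = _state(simple_profile, simple_profile.arr("sat"))
        assert wfps_excess_fraction(simple_profile, at_dul, 450.0) == 0.0
        assert wfps_excess_fraction(simple_profile, at_sat, 450.0) == 1.0

    def test_wfps_thickness_weighted_mean(self):
        prof = SoilProfile(
            (
                SoilLayer(225, 0.2, 0.3, 0.4, 1.4, ks=10.0),
                SoilLayer(225, 0.2, 0.3, 0.4, 1.4, ks=10.0),
            )
        )
        st_ = _state(prof, [0.3, 0.4])
        assert wfps_excess_fraction(prof, st_, 450.0) == pytest.approx(0.5)

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4), st.floats(0.05, 1))
    def test_wfps_monotone_in_water(self, fracs, bump):
        prof = SoilProfile(
            tuple(SoilLayer(150, 0.2, 0.3, 0.4, 1.4, ks=5.0) for _ in range(4))
        )
        ll, sat, dul = prof.arr("ll15"), prof.arr("sat"), prof.arr("dul")
        sw = dul + np.asarray(fracs) * (sat - dul)
        wetter = np.minimum(sat, sw + bump * 0.05)
        lo = wfps_excess_fraction(prof, _state(prof, sw), 450.0)
        hi = wfps_excess_fraction(prof, _state(prof, wetter), 450.0)
        assert hi >= lo - 1e-12

    def test_supply_excludes_saturated_layers(self, simple_profile):
        st_ = _state(simple_profile, simple_profile.arr("sat"))
        assert available_supply(simple_profile, st_, 1200.0) == 0.0

    def test_supply_zero_at_lower_limit(self, simple_profile):
        st_ = _state(simple_profile, simple_profile.arr("ll15"))
        assert available_supply(simple_profile, st_, 1200.0) == 0.0

    def test_supply_single_layer_product(self):
        prof = SoilProfile((SoilLayer(300, 0.20, 0.35, 0.45, 1.4, ks=5.0, kl=0.10),))
        st_ = _state(prof, [0.30])
        assert available_supply(prof, st_, 300.0) == pytest.approx(3.0)

    def test_air_filled_porosity(self, simple_profile):
        st_ = _state(simple_profile, [0.37, 0.30, 0.30, 0.30])
        assert air_filled_porosity_at(simple_profile, st_, 100.0) == pytest.approx(0.03)
        with pytest.raises(ValueError):
            air_filled_porosity_at(simple_profile, st_, 5000.0)


class TestMineralN:
    def test_uptake_excludes_saturated(self, simple_profile):
        st_ = SoilWaterState(
            sw=simple_profile.arr("sat").copy(),
            mineral_n=np.full(4, 10.0),
        )
        assert accessible_mineral_n(simple_profile, st_, 1200.0) == 0.0

    def test_uptake_removes_mass(self, simple_profile, simple_state):
        acc = accessible_mineral_n(simple_profile, simple_state, 1200.0)
        out = take_up_mineral_n(simple_profile, simple_state, 1200.0, acc)
        assert out.mineral_n.sum() == pytest.approx(
            simple_state.mineral_n.sum() - acc
        )
        assert np.all(out.mineral_n >= 0)

    def test_denitrification_only_in_saturated(self, simple_profile):
        sw = simple_profile.arr("dul").copy()
        sw[3] = simple_profile.arr("sat")[3]
        st_ = SoilWaterState(sw=sw, mineral_n=np.full(4, 10.0))
        out = step_mineral_n(simple_profile, st_, 0.0, 0.10)
        np.testing.assert_allclose(out.mineral_n[:3], 10.0)
        assert out.mineral_n[3] == pytest.approx(9.0)

    def test_mineralization_feeds_top_layer(self, simple_profile, simple_state):
        out = step_mineral_n(simple_profile, simple_state, 1.5, 0.0)
        assert out.mineral_n[0] == pytest.approx(simple_state.mineral_n[0] + 1.5)
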