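import numpy as np
import pytest
from hypothesis import given, strategies as st

from divegas.respiratory import (
    ComplianceParams,
    RespiratoryModel,
    RespiratoryState,
    compartment_volumes,
    pressure_at_depth,
    shunt_fraction,
    total_lung_capacity,
)

UPDATED = ComplianceParams.load("updated_dolphin")
LEGACY = ComplianceParams.load("legacy")


class TestPressureAtDepth:
    @pytest.mark.parametrize("depth,ata", [(0.0, 1.0), (1.5, 1.15), (10.0, 2.0), (150.0, 16.0)])
    def test_hydrostatic_conversion(self, depth, ata):
        assert pressure_at_depth(depth) == pytest.approx(ata)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            pressure_at_depth(-0.1)


class TestTotalLungCapacity:
    def test_unit_mass(self):
        tlc, va, vd = total_lung_capacity(1.0)
        assert tlc == pytest.approx(0.135)
        assert va + vd == pytest.approx(tlc)

    def test_reference_animal(self):
        tlc, va, vd = total_lung_capacity(200.0)
        assert tlc == pytest.approx(0.135 * 200.0 ** 0.92)
        assert tlc == pytest.approx(17.67, abs=0.01)
        assert vd == pytest.approx(0.07 * tlc)
        assert vd == pytest.approx(1.24, abs=0.01)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            total_lung_capacity(0.0)


class TestShuntFraction:
    def test_collapse_limit_is_total_shunt(self):
        assert shunt_fraction(0.0, 10.0) == 1.0

    def test_full_inflation_no_shunt(self):
        assert shunt_fraction(10.0, 10.0) == 0.0

    def test_linear_exponent_half_volume(self):
        assert shunt_fraction(5.0, 10.0, gamma=1.0) == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            shunt_fraction(11.0, 10.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.sampled_from([0.1, 0.5, 1.0, 2.0]))
    def test_monotone_nonincreasing_in_volume(self, r1, r2, gamma):
        lo, hi = sorted((r1, r2))
        assert shunt_fraction(lo * 10, 10.0, gamma) >= shunt_fraction(hi * 10, 10.0, gamma)


class TestCompartmentVolumes:
    def test_surface_no_compression(self):
        st_ = compartment_volumes(1.0, UPDATED, dive_start_volume=17.0)
        assert st_.v_alv + st_.v_dead == pytest.approx(17.0)
        assert not st_.collapsed
        assert st_.shunt == 0.0

    def test_extreme_pressure_collapses(self):
        st_ = compartment_volumes(200.0, UPDATED, dive_start_volume=17.0)
        assert st_.collapsed
        assert st_.shunt == 1.0
        assert st_.v_alv < 0.01

    def test_updated_more_compliant_than_legacy_midrange(self):
        """Dolphin-fit parameters compress the alveolar space at shallower
        pressure than the legacy multi-species set, at every test pressure."""
        for pressure in np.linspace(1.2, 30.0, 40):
            v_upd = compartment_volumes(pressure, UPDATED, 17.0)
            v_leg = compartment_volumes(pressure, LEGACY, 17.0)
            assert v_upd.v_alv <= v_leg.v_alv + 1e-12
            assert v_upd.v_dead >= v_leg.v_dead - 1e-12  # stiffer upper airway

    def test_volume_monotone_in_pressure(self):
        pressures = np.linspace(1.0, 60.0, 120)
        states = [compartment_volumes(p, UPDATED, 17.0) for p in pressures]
        v_alv = np.array([s.v_alv for s in states])
        shunts = np.array([s.shunt for s in states])
        assert np.all(np.diff(v_alv) <= 1e-12)
        assert np.all(np.diff(shunts) >= -1e-12)
        assert np.all((shunts >= 0) & (shunts <= 1))

    def test_boyle_conservation(self):
        """Compressed alveolar + dead-space volume matches Boyle's law."""
        for pressure in (1.5, 3.0, 8.0):
            st_ = compartment_volumes(pressure, UPDATED, 17.0)
            assert st_.v_alv + st_.v_dead == pytest.approx(17.0 / pressure, abs=1e-8)

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(ValueError):
            compartment_volumes(0.9, UPDATED, 17.0)
        with pytest.raises(ValueError):
            compartment_volumes(2.0, UPDATED, -1.0)
        with pytest.raises(ValueError):
            compartment_volumes(2.0, UPDATED, 30.0, body_mass=200.0)  # above TLC


class TestRespiratoryModel:
    def test_grid_lookup_matches_exact_solver(self):
        tlc, va, vd = total_lung_capacity(200.0)
        model = RespiratoryModel(UPDATED, va, vd)
        for pressure in np.linspace(1.0, 40.0, 37):
            exact = model.state_at(pressure)
            v_alv, v_dead, s, col = model.lookup(pressure, tlc)
            assert v_alv == pytest.approx(exact.v_alv, abs=2e-4)
            assert v_dead == pytest.approx(exact.v_dead, abs=2e-4)
            assert col == exact.collapsed

    def test_collapse_and_recruitment_pressure_symmetric(self):
        """The model is memoryless in pressure: scanning pressure up then
        down crosses atelectasis at the same ambient pressure."""
        tlc, va, vd = total_lung_capacity(200.0)
        model = RespiratoryModel(UPDATED, va, vd)
        pressures = np.linspace(1.0, 40.0, 2000)
        collapsed_up = np.array([model.state_at(p).collapsed for p in pressures])
        collapsed_down = np.array([model.state_at(p).collapsed for p in pressures[::-1]])[::-1]
        assert np.array_equal(collapsed_up, collapsed_down)
        assert collapsed_up.any() and not collapsed_up.all()

    def test_collapsed_state_invariant(self):
        with pytest.raises(ValueError, match="shunt = 1"):
            RespiratoryState(pressure=20.0, v_alv=0.0, v_dead=0.5, shunt=0.5, collapsed=True)
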