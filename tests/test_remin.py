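"""Redox cascade process functions: printed-constant evaluations, analytic
edge cases, monotonicity sweeps and partition conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfixbox import remin as rx
from nfixbox.params import RedoxParams


class TestWcDenitFraction:
    def test_unity_at_zero_oxygen(self):
        # the two exponential terms cancel exactly at O2 = 0
        assert rx.wc_denit_fraction(0.0) == pytest.approx(1.0, abs=1e-15)

    def test_half_threshold_value(self):
        # O2 = 3.75: (2 - e^-3.75)^-1
        expected = 1.0 / (2.0 - np.exp(-3.75))
        assert rx.wc_denit_fraction(3.75) == pytest.approx(expected)
        assert expected == pytest.approx(0.50595, abs=5e-6)

    def test_negligible_in_oxygenated_water(self):
        assert rx.wc_denit_fraction(20.0) == pytest.approx(8.8e-8, rel=0.01)

    @given(st.floats(0, 300))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_positive(self, o2):
        f = rx.wc_denit_fraction(o2)
        assert 0.0 < f <= 1.0

    def test_strictly_decreasing_in_o2(self):
        o2 = np.linspace(0.0, 60.0, 2000)
        f = rx.wc_denit_fraction(o2)
        assert np.all(np.diff(f) < 0)


class TestNo3Limiter:
    def test_tanh_zero_argument(self):
        # NO3 = 40 with the default floor 30: argument 0 -> 0.5
        assert rx.wc_denit_no3_limiter(40.0) == pytest.approx(0.5)

    def test_at_the_floor(self):
        assert rx.wc_denit_no3_limiter(30.0) == pytest.approx(
            0.5 + 0.5 * np.tanh(-2.5))
        assert rx.wc_denit_no3_limiter(30.0) == pytest.approx(0.006693, abs=1e-6)

    def test_open_at_high_no3(self):
        assert rx.wc_denit_no3_limiter(60.0) == pytest.approx(0.99995, abs=1e-5)

    def test_cap_is_hard_minimum(self):
        # anoxic water, scarce NO3: the limiter caps f_den
        f = rx.effective_wc_denit_fraction(0.0, 30.0)
        assert f == pytest.approx(rx.wc_denit_no3_limiter(30.0))

    def test_monotone_increasing(self):
        no3 = np.linspace(0.0, 80.0, 1000)
        assert np.all(np.diff(rx.wc_denit_no3_limiter(no3)) > 0)


class TestWcDenitRemoval:
    def test_full_denitrification_of_diazotroph_matter(self):
        assert rx.wc_denit_no3_removal(1.0, 1.0, 294.8) == pytest.approx(294.8)

    def test_zero_fraction(self):
        assert rx.wc_denit_no3_removal(0.0, 5.0, 294.8) == 0.0

    def test_general_matter_uses_its_own_closure(self):
        from nfixbox.params import paulmier_closure
        _, n_rem = paulmier_closure(106.0, 16.0)
        assert rx.wc_denit_no3_removal(1.0, 1.0, n_rem) == pytest.approx(94.4)


class TestSedimentDenitrification:
    def test_factor_at_equal_o2_no3(self):
        # 0.98^0 = 1 -> alpha + beta = 0.18, r_Sden at NO3 >= 1 is ~1
        f = rx.sed_denit_factor(50.0, 50.0)
        assert f == pytest.approx(0.18, rel=1e-6)

    def test_oxygen_excess_suppresses(self):
        f = rx.sed_denit_factor(100.0, 0.5)
        # 0.08 + 0.1*0.98^99.5 at r_Sden(0.5) = 0.5
        expected = (0.08 + 0.1 * 0.98**99.5) * 0.5
        assert f == pytest.approx(expected)
        assert 0.08 + 0.1 * 0.98**100 == pytest.approx(0.09326, abs=5e-6)

    def test_no3_scaling_tanh_points(self):
        assert rx.sed_denit_no3_scaling(0.5) == pytest.approx(0.5)
        assert rx.sed_denit_no3_scaling(0.0) == pytest.approx(4.54e-5,
                                                             rel=0.01)

    def test_monotone_in_no3(self):
        no3 = np.linspace(0.0, 2.0, 500)
        assert np.all(np.diff(rx.sed_denit_no3_scaling(no3)) > 0)


class TestSedimentAerobic:
    def test_tanh_zero_at_25(self):
        assert rx.sed_aerobic_scaling(25.0) == pytest.approx(0.5)

    def test_near_open_at_hypoxia_threshold(self):
        assert rx.sed_aerobic_scaling(40.0) == pytest.approx(0.99752, abs=1e-5)

    def test_closed_in_anoxia(self):
        assert rx.sed_aerobic_scaling(0.0) == pytest.approx(4.54e-5, rel=0.01)

    def test_monotone_increasing(self):
        o2 = np.linspace(0.0, 80.0, 500)
        assert np.all(np.diff(rx.sed_aerobic_scaling(o2)) > 0)


class TestSinkingPartition:
    def test_no_contact_all_water_column(self):
        sed, wc, leaving = rx.sinking_flux_partition(1.0, [0.0, 0.0, 0.0])
        assert np.all(sed == 0)
        assert leaving == pytest.approx(1.0)

    def test_full_interception_at_first_level(self):
        sed, wc, leaving = rx.sinking_flux_partition(2.0, [1.0, 0.5])
        assert sed[0] == pytest.approx(2.0)
        assert sed[1] == 0.0
        assert leaving == 0.0

    def test_telescoping_example(self):
        # fractions (0.2, 0.3, 1.0): deliveries 0.2, 0.24, 0.56
        sed, wc, leaving = rx.sinking_flux_partition(1.0, [0.2, 0.3, 1.0])
        np.testing.assert_allclose(sed, [0.2, 0.24, 0.56])
        assert leaving == 0.0
        assert wc.sum() == 0.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6),
           st.floats(0, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_partition_conserves_flux(self, fractions, export):
        att = np.full(len(fractions), 0.5)
        sed, wc, leaving = rx.sinking_flux_partition(export, fractions, att)
        assert sed.sum() + wc.sum() + leaving == pytest.approx(
            export, rel=1e-12, abs=1e-9)

    def test_martin_attenuation_pass_fraction(self):
        # 100 -> 1000 m at b = 0.9 passes 10^-0.9 of the flux
        assert rx.sinking_attenuation(100.0, 1000.0, 0.9) == pytest.approx(
            10 ** -0.9)


class TestSuboxicFraction:
    def test_fully_oxygenated(self):
        o2 = np.full(4, 200.0)
        vol = np.ones(4)
        assert rx.suboxic_fraction(o2, vol) == 0.0

    def test_single_box_share(self):
        o2 = np.array([200.0, 5.0, 200.0])
        vol = np.array([9.5, 0.5, 0.0])
        assert rx.suboxic_fraction(o2, vol) == pytest.approx(5.0)

    def test_threshold_is_strict(self):
        o2 = np.array([10.0])
        assert rx.suboxic_fraction(o2, np.ones(1)) == 0.0
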