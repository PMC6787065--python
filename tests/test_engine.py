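"""Time-stepping contracts: conservation, process attribution, analytic
relaxation, and the column remineralisation budget."""

import numpy as np
import pytest

from nfixbox.engine import Model, StepTendency
from nfixbox.state import TRACERS, TracerState, total_inventory


@pytest.fixture(scope="module")
def mild_model():
    return Model(state_name="mild", dt=0.1)


class TestStepContracts:
    def test_uniform_tracers_transport_null(self, mild_model):
        """Transport of a uniform field changes nothing (to machine
        precision)."""
        s = mild_model.initial_state(warm_start=False)
        _, tend, _ = mild_model.step(s, 0.0)
        for name in ("po4", "dic", "alk"):
            d = tend.deltas["transport"][name]
            assert np.max(np.abs(d)) < 1e-9

    def test_process_attribution_sums_to_state_change(self, mild_model):
        s = mild_model.initial_state()
        for i in range(3):
            s2, tend, _ = mild_model.step(s, i * 0.1)
            for name in TRACERS:
                total = tend.total(name, mild_model.geometry.n_box)
                expected = getattr(s, name) + total
                # clipping to zero is the only allowed divergence
                expected = np.maximum(expected, 0.0) if name != "age" \
                    else expected
                if name == "no3_15":
                    expected = np.minimum(expected, s2.no3)
                np.testing.assert_allclose(getattr(s2, name), expected,
                                           rtol=0, atol=1e-10)
            s = s2

    def test_phosphorus_conserved(self, mild_model):
        """No P sources or sinks exist: total P constant to 1e-10
        relative over many steps with full biology."""
        s = mild_model.initial_state()
        p0 = total_inventory(s, mild_model.geometry, "po4")
        for i in range(50):
            s, _, _ = mild_model.step(s, i * 0.1)
        p1 = total_inventory(s, mild_model.geometry, "po4")
        assert abs(p1 - p0) / p0 < 1e-10

    def test_invalid_dt_rejected(self, mild_model):
        with pytest.raises(ValueError):
            mild_model.step(mild_model.initial_state(), 0.0, dt=-0.1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            Model(diazotroph_mode="double")

    def test_reproducible_stepping(self):
        m1 = Model(state_name="mild", dt=0.1)
        m2 = Model(state_name="mild", dt=0.1)
        s1 = m1.initial_state()
        s2 = m2.initial_state()
        for i in range(5):
            s1, _, _ = m1.step(s1, i * 0.1)
            s2, _, _ = m2.step(s2, i * 0.1)
        for name in TRACERS:
            np.testing.assert_array_equal(getattr(s1, name),
                                          getattr(s2, name))


class TestIronRelaxation:
    def test_closed_form_exponential_approach(self):
        """With every box relaxed, biology and deposition silenced, a
        uniform Fe field approaches 0.6 umol/m3 as 0.6 - 0.4 e^-t
        (tau = 1 yr); transport cannot perturb a uniform field."""
        m = Model(state_name="mild", dt=0.1)
        m.params.general.s_etop = 0.0
        m.dz_params = type(m.dz_params)(s_etop=1e-300)
        m._fe_dep[:] = 0.0
        m.geometry.fe_relax_mask[:] = True
        s = m.initial_state(warm_start=False, fe=0.2)
        for i in range(10):
            s, _, _ = m.step(s, i * 0.1)
        expected = 0.6 - 0.4 * np.exp(-1.0)
        np.testing.assert_allclose(s.fe, expected, rtol=1e-8)
        assert expected == pytest.approx(0.4528, abs=2e-4)

    def test_single_box_relaxation_update_closed_form(self, geometry):
        """relaxation_update composed over a year matches the analytic
        exponential solution of dFe/dt = (0.6 - Fe)/tau."""
        from nfixbox.iron import relaxation_update
        from nfixbox.params import FeParams
        fe = np.full(geometry.n_box, 0.2)
        p = FeParams()
        for _ in range(100):
            fe, _ = relaxation_update(fe, geometry, p, 0.01)
        relax = geometry.fe_relax_mask
        np.testing.assert_allclose(fe[relax], 0.6 - 0.4 * np.exp(-1.0),
                                   rtol=1e-12)
        np.testing.assert_allclose(fe[~relax], 0.2)

    def test_relaxation_is_sink_above_target(self):
        m = Model(state_name="mild", dt=0.1)
        s = m.initial_state(warm_start=False, fe=1.0)
        _, tend, _ = m.step(s, 0.0)
        relax = m.geometry.fe_relax_mask
        assert np.all(tend.deltas["fe_relax"]["fe"][relax] < 0)

    def test_fixed_point_at_target(self):
        m = Model(state_name="mild", dt=0.1)
        s = m.initial_state(warm_start=False, fe=0.6)
        _, tend, _ = m.step(s, 0.0)
        np.testing.assert_allclose(tend.deltas["fe_relax"]["fe"], 0.0,
                                   atol=1e-15)


class TestNitrogenBudget:
    def test_n_change_equals_sources_minus_sinks(self, mild_model):
        """Per step, d(total N) = fixation + deposition - denitrification
        (including the organic N lost through the denitrifying pathways)."""
        m = Model(state_name="mild", dt=0.1)
        s = m.initial_state()
        for i in range(5):
            s, _, _ = m.step(s, i * 0.1)
        g = m.geometry
        n0 = total_inventory(s, g, "no3")
        s2, tend, diag = m.step(s, 0.5)
        n1 = total_inventory(s2, g, "no3")
        dt = 0.1
        expected = (diag["fixation_mol_yr"] + diag["n_dep_mol_yr"]
                    - diag["wc_denit_mol_yr"] - diag["sed_denit_mol_yr"]
                    - diag["denit_org_n_mol_yr"]) * dt
        assert n1 - n0 == pytest.approx(expected, rel=1e-6)

    def test_15n_is_subset_of_n(self, mild_model):
        s = mild_model.initial_state()
        for i in range(20):
            s, _, _ = mild_model.step(s, i * 0.1)
        assert np.all(s.no3_15 <= s.no3 + 1e-12)
        s.validate()

    def test_off_mode_freezes_n_inventory(self):
        m = Model(state_name="mild", diazotroph_mode="off", dt=0.1)
        s = m.initial_state()
        g = m.geometry
        n0 = total_inventory(s, g, "no3")
        for i in range(30):
            s, _, diag = m.step(s, i * 0.1)
        assert diag["fixation_mol_yr"] == 0.0
        assert diag["wc_denit_mol_yr"] == 0.0
        assert diag["sed_denit_mol_yr"] == 0.0
        n1 = total_inventory(s, g, "no3")
        assert abs(n1 - n0) / n0 < 1e-10


class TestCarbonClosure:
    def test_free_atmosphere_carbon_conserved(self):
        """Ocean DIC + atmosphere CO2 is closed under a free atmosphere
        (biology only redistributes carbon)."""
        from nfixbox.carbonate import AtmosphereBox
        m = Model(state_name="mild", dt=0.1,
                  atmosphere=AtmosphereBox(280.0, "free"))
        s = m.initial_state()
        g = m.geometry
        c0 = total_inventory(s, g, "dic") + m.atmosphere.co2_moles
        years = 20
        for i in range(int(years / 0.1)):
            s, _, _ = m.step(s, i * 0.1)
        c1 = total_inventory(s, g, "dic") + m.atmosphere.co2_moles
        # contract: 1e-8 relative per millennium
        assert abs(c1 - c0) / c0 < 1e-8 * (years / 1000.0) + 1e-12


class TestTotalInventory:
    def test_uniform_concentration(self, geometry):
        s = TracerState.initial(geometry.n_box, po4=1.0)
        # 1 mmol/m3 over 1.33e18 m3 -> 1.33e15 mol
        assert total_inventory(s, geometry, "po4") == pytest.approx(
            1.33e15, rel=1e-3)

    def test_dic_in_pg(self, geometry):
        s = TracerState.initial(geometry.n_box, dic=1.0)
        mol = total_inventory(s, geometry, "dic")
        pg = total_inventory(s, geometry, "dic", units="pg_c")
        assert pg == pytest.approx(mol * 12.011e-15)

    def test_unknown_tracer(self, geometry):
        s = TracerState.initial(geometry.n_box)
        with pytest.raises(KeyError):
            total_inventory(s, geometry, "si")

    def test_empty_geometry_rejected(self, geometry):
        import dataclasses
        empty = dataclasses.replace(geometry, tags=[],
                                    volume=np.array([]))
        s = TracerState.initial(16)
        with pytest.raises(ValueError):
            total_inventory(s, empty, "po4")


class TestStepTendency:
    def test_total_accumulates_processes(self):
        t = StepTendency()
        t.add("a", "po4", np.array([1.0, 2.0]))
        t.add("b", "po4", np.array([0.5, -1.0]))
        np.testing.assert_array_equal(t.total("po4", 2),
                                      np.array([1.5, 1.0]))
        np.testing.assert_array_equal(t.total("no3", 2), np.zeros(2))
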