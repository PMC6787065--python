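"""Synthetic physical state: geometry construction, circulation
conservation and Table-style ranking of the four states, deposition
forcings."""

import numpy as np
import pytest

from nfixbox.circulation import (STATE_NAMES, ideal_age_steady,
                                 make_circulation)
from nfixbox.forcing import (make_climatology, make_fe_deposition,
                             make_n_deposition)
from nfixbox.geometry import default_config, make_geometry
from nfixbox.units import MOL_PER_TG_N, SV_TO_M3_PER_YEAR


class TestGeometry:
    def test_total_volume(self, geometry):
        assert geometry.total_volume == pytest.approx(1.33e18, rel=1e-3)

    def test_sediment_fractions_in_unit_interval(self, geometry):
        f = geometry.sediment_contact_fraction
        assert np.all((f >= 0) & (f <= 1))

    def test_eastern_thermocline_has_largest_shelf_contact(self, geometry):
        """The eastern tropical thermocline emulates the widest shelves."""
        thermo = [i for i, t in enumerate(geometry.tags)
                  if t.startswith("thermocline")]
        east = geometry.index("thermocline_east")
        f = geometry.sediment_contact_fraction
        assert all(f[east] >= f[i] for i in thermo)
        assert f[east] > f[geometry.index("thermocline_west")]

    def test_deterministic_construction(self):
        g1 = make_geometry()
        g2 = make_geometry()
        np.testing.assert_array_equal(g1.volume, g2.volume)
        np.testing.assert_array_equal(g1.sediment_contact_fraction,
                                      g2.sediment_contact_fraction)

    def test_requires_twelve_boxes(self):
        cfg = default_config()
        cfg["boxes"] = cfg["boxes"][:11]
        with pytest.raises(ValueError):
            make_geometry(cfg)

    def test_volume_mismatch_rejected(self):
        cfg = default_config()
        cfg["boxes"][0][1] *= 40.0
        with pytest.raises(ValueError):
            make_geometry(cfg)

    def test_columns_end_at_full_interception(self, geometry):
        for path in geometry.columns.values():
            last_box = path[-1][0]
            assert geometry.sediment_contact_fraction[last_box] == 1.0


class TestCirculation:
    @pytest.mark.parametrize("state, aabw, nadw", [
        ("warm", 7.2, 20.3), ("mild", 11.5, 18.4),
        ("cool", 11.4, 13.0), ("cold", 39.0, 13.0),
    ])
    def test_overturning_magnitudes(self, state, aabw, nadw):
        c = make_circulation(state)
        assert c.psi_aabw_sv == pytest.approx(aabw)
        assert c.psi_nadw_sv == pytest.approx(nadw)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            make_circulation("pliocene")

    def test_volume_conservation_exact(self, geometry):
        for state in STATE_NAMES:
            inflow, outflow = make_circulation(state).box_inflow_outflow(
                geometry)
            np.testing.assert_allclose(inflow, outflow, rtol=1e-12)

    def test_uniform_field_has_null_tendency(self, geometry):
        for state in STATE_NAMES:
            m = make_circulation(state).transport_matrix(geometry)
            tend = m @ np.full(geometry.n_box, 3.7)
            # scale: typical box turnover is O(1) per year, so this is
            # machine-precision null
            assert np.max(np.abs(tend)) < 1e-12

    def test_all_transports_non_negative(self, geometry):
        for state in STATE_NAMES:
            c = make_circulation(state)
            assert all(sv >= 0 for _, _, sv in c.edges)
            assert all(sv >= 0 for _, _, sv in c.mixing)

    def test_upwelling_ranked_warm_to_cold(self):
        u = {s: make_circulation(s).upwelling_sv for s in STATE_NAMES}
        assert u["warm"] > u["mild"] >= u["cool"] > u["cold"]

    def test_cold_state_oldest_ideal_age(self, geometry):
        """Volume-mean steady ideal age ranks the cold (glacial) state as
        the least ventilated of the four, despite its strong lower cell:
        most of that cell recirculates at depth."""
        ages = {}
        for state in STATE_NAMES:
            a = ideal_age_steady(make_circulation(state), geometry)
            ages[state] = float((a * geometry.volume).sum()
                                / geometry.volume.sum())
        assert all(ages["cold"] > ages[s] for s in ("warm", "mild", "cool"))


class TestClimatology:
    def test_mean_temperature_matches_states(self, geometry):
        targets = {"warm": 5.3, "mild": 3.9, "cool": 3.5, "cold": 1.4}
        for state, target in targets.items():
            clim = make_climatology(geometry, state)
            assert clim.volume_mean_temp(geometry) == pytest.approx(
                target, abs=0.05)

    def test_temperature_ranking(self, geometry):
        means = {s: make_climatology(geometry, s).volume_mean_temp(geometry)
                 for s in STATE_NAMES}
        assert means["warm"] > means["mild"] > means["cool"] > means["cold"]

    def test_ice_fraction_bounds(self, geometry):
        for state in STATE_NAMES:
            ico = make_climatology(geometry, state).ico_monthly
            assert np.all((ico >= 0) & (ico <= 1))

    def test_no_temperature_below_freezing(self, geometry):
        for state in STATE_NAMES:
            assert make_climatology(geometry, state).temp_monthly.min() >= -1.9


class TestFeDeposition:
    def test_constant_factor_scaling(self, geometry):
        full = make_fe_deposition(geometry, "modern", 100)
        half = make_fe_deposition(geometry, "modern", 50)
        np.testing.assert_allclose(half.flux, 0.5 * full.flux, rtol=1e-12)

    def test_glacial_global_integral_is_five_fold(self, geometry):
        modern = make_fe_deposition(geometry, "modern", 100)
        glacial = make_fe_deposition(geometry, "glacial", 500)
        ratio = glacial.global_integral(geometry) / modern.global_integral(
            geometry)
        assert ratio == pytest.approx(5.0, rel=0.01)

    def test_glacial_tropical_pacific_roughly_two_fold(self, geometry):
        modern = make_fe_deposition(geometry, "modern", 100)
        glacial = make_fe_deposition(geometry, "glacial", 500)
        surf_tags = [geometry.tags[i] for i in glacial.surface_indices]
        for region in ("trop_pac_east_surface", "trop_pac_west_surface"):
            j = surf_tags.index(region)
            ratio = glacial.flux[j] / modern.flux[j]
            assert ratio == pytest.approx(2.0, rel=0.2)

    def test_modern_pattern_low_in_east_pacific(self, geometry):
        f = make_fe_deposition(geometry, "modern", 100)
        surf_tags = [geometry.tags[i] for i in f.surface_indices]
        east = f.flux[surf_tags.index("trop_pac_east_surface")]
        assert east < f.flux[surf_tags.index("npac_surface")]
        assert east < f.flux[surf_tags.index("natl_surface")]

    def test_invalid_scale_pattern_combinations(self, geometry):
        with pytest.raises(ValueError):
            make_fe_deposition(geometry, "modern", 500)
        with pytest.raises(ValueError):
            make_fe_deposition(geometry, "glacial", 100)
        with pytest.raises(ValueError):
            make_fe_deposition(geometry, "lgm", 100)

    def test_2500_is_five_times_500(self, geometry):
        g500 = make_fe_deposition(geometry, "glacial", 500)
        g2500 = make_fe_deposition(geometry, "glacial", 2500)
        np.testing.assert_allclose(g2500.flux, 5.0 * g500.flux, rtol=1e-12)


class TestNDeposition:
    def test_annual_integral_exact(self, geometry):
        ndep = make_n_deposition(geometry)
        assert ndep.annual_integral_tg(geometry) == pytest.approx(
            11.3, rel=1e-6)

    def test_renormalised_for_any_geometry(self, geometry):
        cfg = default_config()
        for row in cfg["boxes"]:
            row[2] *= 2.0          # double all areas
        cfg["total_volume"] = sum(r[1] for r in cfg["boxes"]) * 1e16
        # volumes unchanged: thickness halves but integral renormalises
        g2 = make_geometry(cfg)
        assert make_n_deposition(g2).annual_integral_tg(g2) == pytest.approx(
            11.3, rel=1e-6)

    def test_monthly_rates_average_to_annual(self, geometry):
        ndep = make_n_deposition(geometry)
        area = geometry.area[ndep.surface_indices]
        monthly_mol = (ndep.flux_monthly * area).sum(axis=1) / 12.0
        assert monthly_mol.sum() == pytest.approx(11.3 * MOL_PER_TG_N,
                                                  rel=1e-9)

    def test_deterministic(self, geometry):
        a = make_n_deposition(geometry).flux_monthly
        b = make_n_deposition(geometry).flux_monthly
        np.testing.assert_array_equal(a, b)
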