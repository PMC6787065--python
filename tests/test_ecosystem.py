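"""Export-production parameterisation: exactness against an independent
symbolic evaluation, analytic special points, and bound/niche properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfixbox.ecosystem import (SurfaceEnvironment, calcifier_production,
                               diazotroph_export, diazotroph_growth_rate,
                               diazotroph_limitations, general_export)
from nfixbox.params import DiazotrophParams, GeneralPhytoParams


def _env(T=25.0, po4=1.0, no3=0.0, fe=2.0, ico=0.0):
    return SurfaceEnvironment(temperature=T, po4=po4, no3=no3, fe=fe, ico=ico)


class TestGrowthRate:
    def test_floor_active_in_cold_water(self):
        # at 15 degC the quadratic evaluates to -0.3474 -> floored
        assert diazotroph_growth_rate(15.0) == pytest.approx(0.01)
        quad = -0.0042 * 15.0**2 + 0.2253 * 15.0 - 2.7819
        assert quad == pytest.approx(-0.3474)

    def test_vertex_is_global_maximum(self):
        t_star = 0.2253 / (2 * 0.0042)
        assert t_star == pytest.approx(26.8214, abs=1e-3)
        mu_max = diazotroph_growth_rate(t_star)
        assert mu_max == pytest.approx(-0.0042 * t_star**2 + 0.2253 * t_star
                                       - 2.7819)
        # closed form: c - b^2 / (4a)
        assert mu_max == pytest.approx(-2.7819 + 0.2253**2 / (4 * 0.0042),
                                       rel=1e-12)
        assert mu_max == pytest.approx(0.2395, abs=5e-4)
        t = np.linspace(-5.0, 45.0, 2001)
        assert np.all(diazotroph_growth_rate(t) <= mu_max + 1e-12)

    def test_floor_boundaries_match_quadratic_roots(self):
        # roots of quadratic - 0.01, found independently with numpy
        lo, hi = np.sort(np.roots([-0.0042, 0.2253, -2.7819 - 0.01]))
        assert lo == pytest.approx(19.4288, abs=2e-3)
        assert hi == pytest.approx(34.2141, abs=2e-3)
        eps = 1e-6
        assert diazotroph_growth_rate(lo - 0.1) == 0.01
        assert diazotroph_growth_rate(hi + 0.1) == 0.01
        assert diazotroph_growth_rate(lo + 0.1) > 0.01 + eps
        assert diazotroph_growth_rate(hi - 0.1) > 0.01 + eps


class TestLimitations:
    def test_no_nitrate_means_no_inhibition(self):
        _, no3_lim, _ = diazotroph_limitations(_env(no3=0.0),
                                               DiazotrophParams())
        assert no3_lim == pytest.approx(1.0)

    def test_iron_limit_zero_at_half_saturation_over_two(self):
        # tanh(2*0.15 - 0.3) = tanh(0) = 0
        _, _, fe_lim = diazotroph_limitations(_env(fe=0.15),
                                              DiazotrophParams())
        assert fe_lim == 0.0

    @pytest.mark.parametrize("k_po4, expected", [
        (1e-10, 1.0),            # default: effectively unlimited P affinity
        (0.1, 0.5 / 0.6),        # the weakened-affinity ablation value
    ])
    def test_po4_limit(self, k_po4, expected):
        po4_lim, _, _ = diazotroph_limitations(
            _env(po4=0.5), DiazotrophParams(k_po4=k_po4))
        assert po4_lim == pytest.approx(expected, abs=1e-9)

    @given(po4=st.floats(0, 50), no3=st.floats(0, 60), fe=st.floats(0, 20))
    @settings(max_examples=300, deadline=None)
    def test_limits_bounded(self, po4, no3, fe):
        po4_lim, no3_lim, fe_lim = diazotroph_limitations(
            _env(po4=po4, no3=no3, fe=fe), DiazotrophParams())
        assert 0.0 <= po4_lim <= 1.0
        assert 0.0 < no3_lim <= 1.0
        assert 0.0 <= fe_lim <= 1.0


class TestDiazotrophExport:
    def test_ice_shutoff(self):
        p = DiazotrophParams()
        assert diazotroph_export(_env(ico=1.0), p) == 0.0

    def test_inner_floor_applies_to_tiny_limitation(self):
        # NO3 high enough that min(limits) < 0.01 -> the printed inner
        # floor 0.01 is used instead
        p = DiazotrophParams()
        out = diazotroph_export(_env(no3=30.0), p)
        mu = diazotroph_growth_rate(25.0)
        assert out == pytest.approx(p.s_etop * mu * 0.01)

    def test_matches_independent_symbolic_evaluation(self, rng):
        """The coded law equals a sympy re-transcription on random inputs."""
        sympy = pytest.importorskip("sympy")
        T, P, N, F, I = sympy.symbols("T P N F I")
        k_fe, k_po4, s = sympy.Rational(3, 10), sympy.Float(1e-10), \
            sympy.Symbol("s")
        mu = sympy.Max(0.01, -0.0042 * T**2 + 0.2253 * T - 2.7819)
        lim = sympy.Max(0.01, sympy.Min(P / (P + k_po4), sympy.exp(-N),
                                        sympy.Max(0, sympy.tanh(2 * F - k_fe))))
        expr = s * mu * lim * (1 - I)
        f = sympy.lambdify((T, P, N, F, I, sympy.Symbol("s")), expr, "numpy")
        p = DiazotrophParams()
        n = 1000
        T_ = rng.uniform(-2, 35, n)
        P_ = rng.uniform(0, 3, n)
        N_ = rng.uniform(0, 45, n)
        F_ = rng.uniform(0, 3, n)
        I_ = rng.uniform(0, 1, n)
        ours = diazotroph_export(
            SurfaceEnvironment(temperature=T_, po4=P_, no3=N_, fe=F_, ico=I_),
            p)
        theirs = f(T_, P_, N_, F_, I_, p.s_etop)
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_niche_low_no3_favours_diazotrophs(self, rng):
        """With NO3 = 0 and abundant Fe, diazotrophs out-export the general
        group at any PO4 > 0 when given equal rate scales."""
        s = 0.01
        dzp = DiazotrophParams(s_etop=s)
        gp = GeneralPhytoParams(s_etop=s)
        for po4 in rng.uniform(1e-6, 3.0, 50):
            env = _env(T=26.8, po4=float(po4), no3=0.0, fe=3.0)
            p_d = diazotroph_export(env, dzp)
            p_g, _ = general_export(env, gp)
            assert p_d > p_g


class TestGeneralExport:
    def test_no_phosphate_no_export(self):
        p_g, _ = general_export(_env(po4=0.0, no3=5.0), GeneralPhytoParams())
        assert p_g == 0.0

    def test_c_to_p_monotone_non_increasing_in_po4(self):
        gp = GeneralPhytoParams()
        po4 = np.linspace(0.01, 2.5, 500)
        ctop = gp.c_to_p(po4)
        assert np.all(np.diff(ctop) <= 1e-12)

    def test_c_to_p_rises_under_phosphate_scarcity(self):
        """Halving PO4 enriches exported matter in carbon by order 10 units
        (the frugality response the drawdown mechanism relies on)."""
        gp = GeneralPhytoParams()
        shift = gp.c_to_p(1.2) - gp.c_to_p(1.5)
        assert 5.0 < shift < 40.0


class TestCalcifiers:
    def test_pic_is_eight_percent_of_organic_carbon(self):
        assert calcifier_production(1.0, 100.0) == pytest.approx(8.0)
        assert calcifier_production(0.0, 100.0) == 0.0
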