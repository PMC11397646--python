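"""Equilibrium-thermodynamics unit and property tests."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from anomeric import (
    A_OH_CYCLOHEXANE,
    AnomerEquilibrium,
    AValue,
    ThermoConstants,
    a_value_cyclohexane_to_thp,
    a_value_from_population,
    anomeric_stabilization,
    beta_fraction_from_dg,
    delta_g_anomeric,
    dg_from_beta_fraction,
    k_an,
    rae_magnitude,
)
from anomeric.thermo import InvalidPopulationError

PAPER = ThermoConstants(rt_mode="paper_rounded")
EXACT = ThermoConstants(rt_mode="exact")


def _eq(beta, alpha=None, T=298.0):
    return AnomerEquilibrium("x", "DMSO-d6", T, beta, alpha)


class TestEquilibriumType:
    def test_alpha_autofill(self):
        eq = _eq(86.7)
        assert eq.percent_alpha == pytest.approx(13.3)

    @pytest.mark.parametrize("beta,alpha", [(0.0, 100.0), (100.0, 0.0),
                                            (105.0, -5.0), (-1.0, 101.0)])
    def test_rejects_degenerate_populations(self, beta, alpha):
        with pytest.raises(InvalidPopulationError):
            _eq(beta, alpha)

    def test_rejects_inconsistent_sum(self):
        with pytest.raises(InvalidPopulationError):
            _eq(60.0, 60.0)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            _eq(50.0, T=0.0)


class TestKAnAndDeltaG:
    @pytest.mark.parametrize("beta,alpha,expected", [
        (50.0, 50.0, 1.0),
        (86.7, 13.3, 86.7 / 13.3),   # 6.5188...
        (47.1, 52.9, 47.1 / 52.9),   # 0.89036...
    ])
    def test_k_an(self, beta, alpha, expected):
        assert k_an(_eq(beta, alpha)) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("beta,alpha,expected", [
        (50.0, 50.0, 0.0),
        (86.7, 13.3, -0.6 * math.log(86.7 / 13.3)),   # -1.1247
        (47.1, 52.9, -0.6 * math.log(47.1 / 52.9)),   # +0.0697
    ])
    def test_delta_g_paper_rounded(self, beta, alpha, expected):
        assert delta_g_anomeric(_eq(beta, alpha), PAPER) == pytest.approx(
            expected, abs=1e-12)

    def test_delta_g_sign_convention(self):
        """Beta-dominant equilibria have negative dG_an."""
        assert delta_g_anomeric(_eq(86.7, 13.3), PAPER) < 0
        assert delta_g_anomeric(_eq(47.1, 52.9), PAPER) > 0


class TestAValues:
    def test_hydroxyl_worked_value(self):
        """89% equatorial cyclohexanol at 298 K gives A_OH = 1.25 (2 dp)."""
        a = a_value_from_population(89.0, 298.0, PAPER)
        assert round(a.value, 2) == 1.25
        assert a.ring_system == "cyclohexane"

    def test_symmetric_population_is_zero(self):
        assert a_value_from_population(50.0, 298.0, PAPER).value == 0.0

    def test_exact_mode(self):
        a = a_value_from_population(75.0, 298.0, EXACT)
        assert a.value == pytest.approx(1.987e-3 * 298 * math.log(3), rel=1e-12)
        assert round(a.value, 3) == 0.651

    @pytest.mark.parametrize("pct", [0.0, 100.0, -3.0])
    def test_degenerate_population_rejected(self, pct):
        with pytest.raises(InvalidPopulationError):
            a_value_from_population(pct)

    @pytest.mark.parametrize("a_in,expected", [
        (1.25, 1.93), (0.0, 0.02), (2.0, 3.08)])
    def test_thp_extrapolation(self, a_in, expected):
        a = a_value_cyclohexane_to_thp(AValue("X", "cyclohexane", a_in))
        assert round(a.value, 2) == expected
        assert a.ring_system == "tetrahydropyran"

    def test_no_double_thp_conversion(self):
        with pytest.raises(ValueError):
            a_value_cyclohexane_to_thp(AValue("X", "tetrahydropyran", 1.93))


class TestAnomericStabilization:
    def test_reference_tetrahydropyranol(self):
        """47.1/52.9 with A_OH = 1.25 reproduces E_an = 1.32 kcal/mol."""
        res = anomeric_stabilization(_eq(47.1, 52.9), A_OH_CYCLOHEXANE, PAPER)
        assert round(res.e_an, 2) == 1.32
        assert res.mode == "eq4_cyclohexane"

    def test_symmetric_equilibrium_returns_a_value(self):
        res = anomeric_stabilization(_eq(50.0, 50.0), A_OH_CYCLOHEXANE, PAPER)
        assert res.e_an == pytest.approx(1.25)

    def test_beta_dominant_imine(self):
        res = anomeric_stabilization(_eq(86.7, 13.3), A_OH_CYCLOHEXANE, PAPER)
        assert res.e_an == pytest.approx(-0.6 * math.log(86.7 / 13.3) + 1.25,
                                         abs=1e-12)

    @given(beta=st.floats(1.0, 99.0))
    @settings(max_examples=200, deadline=None)
    def test_thp_mode_shift_is_exactly_0_68(self, beta):
        """THP A-value (1.93) raises E_an by exactly 1.93-1.25 = 0.68."""
        eq = _eq(beta)
        e_cyc = anomeric_stabilization(
            eq, AValue("OH", "cyclohexane", 1.25), PAPER).e_an
        e_thp = anomeric_stabilization(
            eq, AValue("OH", "tetrahydropyran", 1.93), PAPER).e_an
        assert e_thp - e_cyc == pytest.approx(0.68, abs=1e-12)

    @given(b1=st.floats(1.0, 99.0), b2=st.floats(1.0, 99.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing_in_beta(self, b1, b2):
        if abs(b1 - b2) < 1e-9:
            return
        e1 = anomeric_stabilization(_eq(b1), A_OH_CYCLOHEXANE, PAPER).e_an
        e2 = anomeric_stabilization(_eq(b2), A_OH_CYCLOHEXANE, PAPER).e_an
        assert (b1 < b2) == (e1 > e2)

    @given(beta=st.floats(0.5, 99.5), a=st.floats(-2.0, 4.0))
    @settings(max_examples=1000, deadline=None)
    def test_decomposition_equals_one_step_oracle(self, beta, a):
        """E_an via dG_an + A equals the direct -RT ln(beta/alpha) + A."""
        eq = _eq(beta)
        via_ops = anomeric_stabilization(eq, AValue("X", "cyclohexane", a),
                                         PAPER).e_an
        direct = -0.6 * math.log(beta / (100.0 - beta)) + a
        assert abs(via_ops - direct) < 1e-12

    @given(beta=st.floats(10.0, 90.0))
    @settings(max_examples=200, deadline=None)
    def test_rounded_vs_exact_rt_within_0_02(self, beta):
        """The rounded RT=0.6 convention shifts dG_an by < 0.02 kcal/mol."""
        eq = _eq(beta)
        d = abs(delta_g_anomeric(eq, PAPER) - delta_g_anomeric(eq, EXACT))
        assert d < 0.02


class TestRAE:
    @pytest.mark.parametrize("ref,imine,expected", [
        (1.32, 1.32, 0.0),
        (1.32, 0.125, 1.195),
        (1.32, -0.6, 1.92),
    ])
    def test_magnitude(self, ref, imine, expected):
        assert rae_magnitude(ref, imine).dg_rae == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            rae_magnitude(float("nan"), 0.0)


class TestBoltzmannBetaFraction:
    def test_zero_dg_is_exactly_50(self):
        assert beta_fraction_from_dg(0.0) == 50.0

    def test_negative_dg_favors_beta(self):
        assert beta_fraction_from_dg(-1.0, 298.0, EXACT) == pytest.approx(
            84.4, abs=0.05)

    def test_range_endpoint(self):
        assert beta_fraction_from_dg(-0.315, 298.0, EXACT) == pytest.approx(
            63.0, abs=0.2)
        assert dg_from_beta_fraction(63.0, 298.0, EXACT) == pytest.approx(
            -1.987e-3 * 298 * math.log(63 / 37), rel=1e-12)

    def test_saturates_smoothly(self):
        assert 0.0 < beta_fraction_from_dg(5.0) < 50.0 < beta_fraction_from_dg(-5.0) < 100.0
        # extreme free energies saturate without overflow
        assert beta_fraction_from_dg(500.0) == pytest.approx(0.0, abs=1e-12)
        assert beta_fraction_from_dg(-500.0) == pytest.approx(100.0, abs=1e-12)

    @given(dg=st.floats(-5.0, 5.0))
    @settings(max_examples=300, deadline=None)
    def test_round_trip(self, dg):
        back = dg_from_beta_fraction(beta_fraction_from_dg(dg, 298.0, EXACT),
                                     298.0, EXACT)
        assert abs(back - dg) < 1e-9

    @given(d1=st.floats(-5.0, 5.0), d2=st.floats(-5.0, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_strictly_decreasing(self, d1, d2):
        if abs(d1 - d2) < 1e-9:
            return
        f1, f2 = beta_fraction_from_dg(d1), beta_fraction_from_dg(d2)
        assert (d1 < d2) == (f1 > f2)

    @pytest.mark.parametrize("pct", [0.0, 100.0])
    def test_inverse_rejects_bounds(self, pct):
        with pytest.raises(InvalidPopulationError):
            dg_from_beta_fraction(pct)
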