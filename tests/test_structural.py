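"""Structural model: clearance equation, infusion superposition, error model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

import remipk as rp
from remipk.structural import concentration, individual_params, residual_sd


def ode_concentration(cl, v, doses, t_eval):
    """Brute-force oracle: integrate dA/dt = R(t) - k A and report 1000*A/V."""
    k = cl / v

    def rate(t):
        return sum(d.rate for d in doses if d.start_time <= t < d.end_time)

    def rhs(t, a):
        return [rate(t) - k * a[0]]

    t_eval = np.atleast_1d(t_eval)
    t_pts = sorted({0.0, *[d.start_time for d in doses], *[d.end_time for d in doses],
                    *t_eval.tolist()})
    sol = solve_ivp(rhs, (0.0, max(t_pts)), [0.0], t_eval=t_eval,
                    max_step=0.002, rtol=1e-10, atol=1e-12)
    return 1000.0 * sol.y[0] / v


class TestClearanceEquation:
    def test_reference_female(self, final_model, female_ref):
        assert rp.typical_clearance(final_model, female_ref) == pytest.approx(366.0)

    def test_reference_male(self, final_model, male_ref):
        assert rp.typical_clearance(final_model, male_ref) == pytest.approx(183.732)

    def test_power_term_vanishes_at_center(self, female_ref):
        from remipk.covariates import CovariateEffect
        for exponent in (-3.0, 0.7, 2.04, 5.0):
            m = rp.PopulationModel(
                tvcl=100.0, tvv=41.0, sigma_add=0.1,
                effects=(CovariateEffect("cl", "pump_speed", "power", exponent,
                                         center=2350.0),))
            assert rp.typical_clearance(m, female_ref) == pytest.approx(100.0)

    def test_strictly_increasing_in_pump_speed(self, final_model):
        speeds = np.linspace(1500, 3000, 40)
        cls = [rp.typical_clearance(final_model, rp.CovariateRecord(0, s))
               for s in speeds]
        assert np.all(np.diff(cls) > 0)

    def test_missing_required_covariate_rejected(self, final_model):
        from remipk.covariates import CovariateEffect
        m = final_model.add_effect(
            CovariateEffect("cl", "weight", "power", 0.75, center=65.4))
        with pytest.raises(ValueError, match="weight"):
            rp.typical_clearance(m, rp.CovariateRecord(sex=0, pump_speed=2350.0))


class TestIndividualParams:
    def test_eta_zero_gives_typical(self, final_model, male_ref):
        p = individual_params(final_model, male_ref, eta_cl=0.0)
        assert p.cl == pytest.approx(183.732)
        assert p.v == 41.0

    def test_eta_log2_doubles_clearance(self, final_model, female_ref):
        p = individual_params(final_model, female_ref, eta_cl=np.log(2.0))
        assert p.cl == pytest.approx(2 * 366.0)

    def test_volume_carries_no_eta(self, final_model, female_ref):
        for eta in (-1.0, 0.0, 2.0):
            assert individual_params(final_model, female_ref, eta).v == 41.0


class TestConcentration:
    def test_zero_at_time_zero(self):
        p = rp.IndividualParams(cl=200.0, v=40.0, eta_cl=0.0)
        doses = (rp.InfusionEvent(0.0, 0.42, 48.0),)
        assert concentration(p, doses, 0.0) == 0.0

    def test_steady_state_limit(self):
        p = rp.IndividualParams(cl=183.732, v=41.0, eta_cl=0.0)
        doses = (rp.InfusionEvent(0.0, 0.42, 500.0),)
        css = 1000.0 * 0.42 / 183.732
        assert concentration(p, doses, 480.0) == pytest.approx(css, rel=1e-9)
        assert css == pytest.approx(2.286, abs=5e-4)

    def test_post_infusion_decay_value(self):
        # stop after a long run; 5 min later the level has fallen by e^{-k/12}
        p = rp.IndividualParams(cl=366.0, v=41.0, eta_cl=0.0)
        doses = (rp.InfusionEvent(0.0, 0.63, 48.0),)
        k = 366.0 / 41.0
        expected = (1000.0 * 0.63 / 366.0) * np.exp(-k / 12.0)
        got = concentration(p, doses, 48.0 + 5.0 / 60.0)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(0.818, abs=2e-3)

    @pytest.mark.parametrize("cl,v,rate,t", [
        (366.0, 41.0, 0.63, 0.05),
        (183.7, 41.0, 0.42, 0.3),
        (90.0, 25.0, 0.105, 12.0),
        (500.0, 60.0, 0.84, 49.0),
    ])
    def test_closed_form_matches_ode(self, cl, v, rate, t):
        p = rp.IndividualParams(cl=cl, v=v, eta_cl=0.0)
        doses = (rp.InfusionEvent(0.0, rate, 24.0), rp.InfusionEvent(24.0, rate / 2, 24.0))
        closed = concentration(p, doses, t)
        oracle = ode_concentration(cl, v, doses, t)[0]
        assert closed == pytest.approx(oracle, rel=1e-6, abs=1e-10)

    def test_superposition_of_segments(self):
        p = rp.IndividualParams(cl=250.0, v=41.0, eta_cl=0.0)
        seg1 = rp.InfusionEvent(0.0, 0.4, 10.0)
        seg2 = rp.InfusionEvent(10.0, 0.6, 14.0)
        t = np.linspace(0.0, 30.0, 121)
        both = concentration(p, (seg1, seg2), t)
        split = concentration(p, (seg1,), t) + concentration(p, (seg2,), t)
        np.testing.assert_allclose(both, split, rtol=1e-12)

    def test_monotone_during_and_after_infusion(self):
        p = rp.IndividualParams(cl=300.0, v=41.0, eta_cl=0.0)
        doses = (rp.InfusionEvent(0.0, 0.5, 24.0),)
        t_on = np.linspace(0.0, 24.0, 200)
        t_off = np.linspace(24.01, 30.0, 100)
        c_on = concentration(p, doses, t_on)
        c_off = concentration(p, doses, t_off)
        assert np.all(np.diff(c_on) >= 0)
        assert np.all(np.diff(c_off) < 0)
        assert np.all(np.concatenate([c_on, c_off]) >= 0)

    @given(cl=st.floats(50, 800), v=st.floats(10, 120), rate=st.floats(0.05, 1.0),
           t=st.floats(0, 60))
    def test_gradient_matches_finite_difference(self, cl, v, rate, t):
        p = rp.IndividualParams(cl=cl, v=v, eta_cl=0.0)
        doses = (rp.InfusionEvent(0.0, rate, 24.0),)
        _, grad = concentration(p, doses, t, grad=True)
        h = 1e-5 * cl
        up = concentration(rp.IndividualParams(cl + h, v, 0.0), doses, t)
        dn = concentration(rp.IndividualParams(cl - h, v, 0.0), doses, t)
        assert grad == pytest.approx((up - dn) / (2 * h), rel=1e-3, abs=1e-8)


class TestResidualModel:
    def test_additive_floor_at_zero_prediction(self, final_model):
        assert final_model.residual_sd(0.0) == pytest.approx(0.111)

    def test_proportional_only(self):
        assert residual_sd(1.0, sigma_prop=0.387, sigma_add=0.0) == pytest.approx(0.387)

    def test_combined_at_unit_prediction(self, final_model):
        assert final_model.residual_sd(1.0) == pytest.approx(
            np.hypot(0.387, 0.111))
        assert final_model.residual_sd(1.0) == pytest.approx(0.4026, abs=5e-5)
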