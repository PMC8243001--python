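"""Rate functions, closed-form solution, ODE equivalence, decay constraint."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opsinkit import (
    ClampProtocol,
    GatingState,
    O_inf,
    R_inf,
    check_decay_constraint,
    current_closed_form,
    driving_force,
    rectification,
    simulate_clamp_ode,
    state_derivatives,
    tau_O,
    tau_R,
    two_pulse_ratio_curve,
)
from conftest import random_params_in_bounds


class TestRateFunctions:
    def test_tau_O_dark_limit_is_p3(self, rsrs_final):
        # intensity part collapses to the dark limit at I = 0
        p = rsrs_final.with_(tauO_V=(1.0, 0.0, 1e9), combine_O="product")
        assert tau_O(0.0, -60.0, p) == pytest.approx(0.021 * 0.5, rel=1e-6)

    def test_tau_O_reciprocal_sum_hand_value(self, rsrs_final):
        # voltage part 23.14/(1+exp(-(-60+0.39)/13.19)) ~ 0.249 s combined
        # with the 21 ms dark limit by reciprocal addition
        assert tau_O(0.0, -60.0, rsrs_final) == pytest.approx(0.0194, rel=5e-3)

    def test_tau_O_product_with_unit_voltage_part(self, rsrs_final):
        p = rsrs_final.with_(tauO_V=(1.0, 0.0, 1e9), combine_O="product")
        for V in (-80.0, 0.0, 40.0):
            assert tau_O(123.0, V, p) == pytest.approx(
                tau_O(123.0, -999.0, p), rel=1e-6)

    def test_tau_R_dark_limit_is_p1(self, rsrs_final):
        from opsinkit.model import _tauR_I
        # both logistic terms vanish at I = 0, leaving the 10 s dark limit
        assert _tauR_I(0.0, rsrs_final.tauR_I) == pytest.approx(10.0, rel=1e-9)

    def test_tau_R_intensity_part_at_high_irradiance(self, rsrs_final):
        from opsinkit.model import _tauR_I
        assert _tauR_I(3162.0, rsrs_final.tauR_I) == pytest.approx(0.0163, rel=0.02)

    def test_tau_R_single_logistic_when_weight_one(self, rsrs_final):
        from opsinkit.model import _tauR_I
        p6 = list(rsrs_final.tauR_I)
        p6[1] = 1.0
        one = _tauR_I(np.logspace(0, 4, 9), tuple(p6))
        # second logistic carries zero weight: changing (p5, p6) is inert
        p6[4], p6[5] = -5.0, 2.0
        two = _tauR_I(np.logspace(0, 4, 9), tuple(p6))
        np.testing.assert_allclose(one, two, rtol=1e-12)

    def test_O_inf_limits_and_midpoint(self, rsrs_final):
        assert O_inf(0.0, rsrs_final) == 0.0
        assert O_inf(10 ** rsrs_final.Oinf[0], rsrs_final) == pytest.approx(0.5)
        assert O_inf(5500.0, rsrs_final) == pytest.approx(0.641, abs=1e-3)

    def test_R_inf_limits(self, rsrs_final, mm_final):
        assert R_inf(0.0, rsrs_final) == 1.0
        assert R_inf(1e12, rsrs_final) == pytest.approx(1 - 0.77, rel=1e-6)
        assert R_inf(1e12, mm_final) == pytest.approx(0.0013, rel=1e-3)

    def test_driving_force_hand_value_and_zero_crossing(self, rsrs_final):
        assert driving_force(-60.0, rsrs_final) == pytest.approx(-41.0, abs=0.1)
        v0 = rsrs_final.E + rsrs_final.Grect[2] * np.log(rsrs_final.Grect[1])
        assert v0 == pytest.approx(9.9, abs=0.1)
        assert abs(driving_force(v0, rsrs_final)) < 1e-9

    def test_driving_force_ohmic_reversal(self, rsrs_final):
        p = rsrs_final.with_(Grect=(2.0, 1.0, 30.0))
        assert driving_force(p.E, p) == pytest.approx(0.0, abs=1e-12)
        assert driving_force(0.0, rsrs_final.with_(Grect=None, E=0.0)) == 0.0

    def test_rectification_singular_at_reversal(self, rsrs_final):
        with pytest.raises(ValueError):
            rectification(rsrs_final.E, rsrs_final)

    def test_invalid_inputs_rejected(self, rsrs_final):
        with pytest.raises(ValueError):
            tau_O(-1.0, -60.0, rsrs_final)
        with pytest.raises(ValueError):
            tau_O(np.nan, -60.0, rsrs_final)
        with pytest.raises(ValueError):
            O_inf(np.inf, rsrs_final)


class TestStateDerivatives:
    def test_equilibrium_is_fixed_point(self, rsrs_final):
        I = 500.0
        s = GatingState(float(O_inf(I, rsrs_final)), float(R_inf(I, rsrs_final)))
        dO, dR = state_derivatives(s, I, -60.0, rsrs_final)
        assert abs(dO) < 1e-12 and abs(dR) < 1e-12

    def test_dark_steady_state(self, rsrs_final):
        dO, dR = state_derivatives(GatingState(0.0, 1.0), 0.0, -60.0, rsrs_final)
        assert dO == 0.0 and dR == 0.0

    def test_light_onset_signs(self, rsrs_final):
        dO, dR = state_derivatives(GatingState(0.0, 1.0), 1000.0, -60.0, rsrs_final)
        assert dO > 0 and dR < 0


class TestClosedForm:
    def test_zero_before_onset_and_decay_after(self, rsrs_final):
        prot = ClampProtocol(V=-60.0, I=3162.0, t_on=0.1, t_off=0.6, t_end=20.0)
        t = np.linspace(0.0, 20.0, 5001)
        tr = current_closed_form(t, prot, rsrs_final)
        assert np.all(tr.current[t < 0.1] == 0.0)
        assert abs(tr.current[-1]) < 1e-6 * np.abs(tr.current).max()
        assert tr.O[-1] == pytest.approx(0.0, abs=1e-12)
        # R recovers toward 1 with the seconds-scale dark time constant
        post = tr.R[t > 0.6]
        assert np.all(np.diff(post) >= -1e-12) and post[-1] > 0.95

    def test_plateau_readout_is_on_branch_at_toff(self, rsrs_final):
        prot = ClampProtocol(V=-60.0, I=3162.0, t_on=0.05, t_off=0.55, t_end=0.9)
        t = np.arange(0.0, 0.9, 1.5e-4)
        tr = current_closed_form(t, prot, rsrs_final)
        k = np.searchsorted(t, 0.55)
        from opsinkit.model import _gating_on
        O, R = _gating_on(0.5, 3162.0, -60.0, rsrs_final, 0.0, 1.0)
        expect = rsrs_final.g * driving_force(-60.0, rsrs_final) * O * R
        assert tr.current[k - 1] == pytest.approx(expect, rel=1e-6)

    def test_matches_ode_for_fixture(self, rsrs_final):
        prot = ClampProtocol(V=-60.0, I=3162.0, t_on=0.05, t_off=0.55, t_end=0.9)
        t = np.arange(0.0, 0.9, 1.5e-4)
        tr = current_closed_form(t, prot, rsrs_final)
        ode = simulate_clamp_ode(prot, rsrs_final, t_eval=t)
        err = np.abs(tr.current - ode.current).max()
        assert err <= 1e-4 * np.abs(tr.current).max()

    def test_invalid_init_rejected(self):
        with pytest.raises(ValueError):
            GatingState(1.5, 0.5)

    def test_scaling_invariance_g_vs_rectification_gain(self, rsrs_final):
        from opsinkit import normalize_conductance
        prot = ClampProtocol(V=-40.0, I=1000.0, t_on=0.05, t_off=0.55, t_end=0.9)
        t = np.arange(0.0, 0.9, 1e-3)
        alt = normalize_conductance(rsrs_final, g=9.91)
        a = current_closed_form(t, prot, rsrs_final).current
        b = current_closed_form(t, prot, alt).current
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestOde:
    def test_zero_irradiance_is_flat(self, rsrs_final):
        prot = ClampProtocol(V=-60.0, I=0.0, t_on=0.05, t_off=0.55, t_end=0.9)
        tr = simulate_clamp_ode(prot, rsrs_final)
        assert np.allclose(tr.current, 0.0, atol=1e-12)

    def test_ramp_waveform_monotone_opening(self, rsrs_final):
        prot = ClampProtocol(V=-60.0, I=1000.0, t_on=0.0, t_off=0.5, t_end=0.5)
        ramp = lambda t: 2000.0 * t  # reaches 1000 W/m^2 at t_end
        tr = simulate_clamp_ode(prot, rsrs_final, waveform=ramp,
                                t_eval=np.linspace(0, 0.5, 500))
        dO = np.diff(tr.O)
        assert np.all(dO >= -1e-10)

    def test_gating_stays_in_unit_interval(self, rsrs_final):
        prot = ClampProtocol(V=20.0, I=8000.0, t_on=0.01, t_off=0.3, t_end=1.5)
        tr = simulate_clamp_ode(prot, rsrs_final)
        assert np.all((tr.O >= -1e-9) & (tr.O <= 1 + 1e-9))
        assert np.all((tr.R >= -1e-9) & (tr.R <= 1 + 1e-9))


class TestDecayConstraint:
    def test_hand_evaluated_bound(self, rsrs_final):
        # tau_R(0,V)=5 s, tau_O(0,V)=0.02 s -> bound ~ 0.00398
        p = rsrs_final.with_(
            tauR_I=(5.0, 0.5, -1.58, 0.87, 1.96, 0.11),
            tauR_V=(1.0, 0.0, 1e9), combine_R="product",
            tauO_I=(1.81, 1.17, 0.02), tauO_V=(1.0, 0.0, 1e9), combine_O="product",
            Rinf=(1.96, 0.12, 0.99))
        ok, margin = check_decay_constraint(p, -60.0, [1e12])
        assert ok and margin == pytest.approx(0.01 - 0.02 / 5.02, abs=1e-4)

    def test_boundary_fails_strictly(self, rsrs_final):
        p = rsrs_final.with_(Rinf=(1.96, 0.12, 1.0))  # floor at exactly 0
        ok, margin = check_decay_constraint(p, 40.0, [1e15])
        assert not ok

    def test_fixture_passes_on_grid(self, rsrs_final):
        ok, margin = check_decay_constraint(
            rsrs_final, np.arange(-80.0, 41.0, 20.0), np.logspace(2, 4, 5))
        assert ok and margin > 0.2


class TestMonotonicity:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_equilibria_monotone_and_bounded(self, seed):
        p = random_params_in_bounds(np.random.default_rng(seed))
        I = np.logspace(-2, 6, 60)
        o = O_inf(I, p)
        r = R_inf(I, p)
        assert np.all((o >= 0) & (o <= 1)) and np.all((r >= 0) & (r <= 1))
        assert np.all(np.diff(o) >= -1e-12)
        assert np.all(np.diff(r) <= 1e-12)
        from opsinkit.model import _tauR_I
        assert np.all(np.diff(_tauR_I(I, p.tauR_I)) <= 1e-12)
        assert np.all(tau_O(I, -60.0, p) > 0) and np.all(tau_R(I, -60.0, p) > 0)

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_baseline_return_when_constraint_holds(self, seed):
        p = random_params_in_bounds(np.random.default_rng(seed))
        V = -60.0
        ok, _ = check_decay_constraint(p, V, np.logspace(1, 4, 7))
        if not ok:
            return
        prot = ClampProtocol(V=V, I=1000.0, t_on=0.0, t_off=0.5, t_end=0.5 + 10.0)
        t = np.linspace(0.5, 10.5, 2000)
        tr = current_closed_form(t, prot, p)
        mag = np.abs(tr.current)
        assert np.all(np.diff(mag) <= 1e-12 + 1e-9 * mag[:-1])


class TestTwoPulse:
    def test_ratio_limits(self, rsrs_final):
        I, V = 3162.0, -60.0
        long_gap = two_pulse_ratio_curve(rsrs_final, I, V, [500.0])
        assert long_gap[0] == pytest.approx(1.0, abs=1e-3)
        short_gap = two_pulse_ratio_curve(rsrs_final, I, V, [1e-4])
        # restart from near steady state: probe peak ~ plateau of pulse 1
        prot = ClampProtocol(V=V, I=I, t_on=0.0, t_off=0.5, t_end=0.5)
        t = np.arange(0.0, 0.5, 1e-3)
        tr = current_closed_form(t, prot, rsrs_final)
        i_ratio = np.abs(tr.current[-1]) / np.abs(tr.current).max()
        assert short_gap[0] == pytest.approx(i_ratio, rel=0.02)
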