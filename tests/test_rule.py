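"""Unit behavior of the plasticity rule: filters, Hill activations,
moving thresholds, weight dynamics and the standalone trace runner."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glunplast import (PARAM_SETS, PlasticityParams, PlasticityState,
                       filter_conductance, filter_voltage, get_params,
                       hill_activation, run_rule_on_trace, step_plasticity,
                       update_moving_threshold, update_presyn_trace,
                       weight_derivative)
from glunplast.io import generate_fixture_traces

DT = 0.025


class TestFilters:
    def test_conductance_filter_reaches_dc_gain_one(self):
        g = 0.3
        x = 0.0
        for _ in range(int(200.0 / DT)):
            x = filter_conductance(x, g, tau=20.0, dt=DT)
        assert x == pytest.approx(g, rel=1e-4)

    def test_conductance_step_response_at_tau(self):
        x = 0.0
        for _ in range(int(round(20.0 / DT))):
            x = filter_conductance(x, 1.0, tau=20.0, dt=DT)
        assert x == pytest.approx(1.0 - math.exp(-1.0), rel=1e-3)

    def test_conductance_filter_matches_closed_form(self):
        """Piecewise-constant input: the exponential-Euler update must track
        the exact solution to < 0.1%."""
        tau = 20.0
        x = 0.05
        for i in range(int(100.0 / DT)):
            x = filter_conductance(x, 1.0, tau=tau, dt=DT)
            t = (i + 1) * DT
            exact = 1.0 + (0.05 - 1.0) * math.exp(-t / tau)
            assert abs(x - exact) / exact < 1e-3

    def test_voltage_filter_rest_at_threshold_decays_to_zero(self):
        v = 5.0
        for _ in range(int(200.0 / DT)):
            v = filter_voltage(v, -65.0, theta=-65.0, tau=10.0, dt=DT)
        assert v == pytest.approx(0.0, abs=1e-6)

    def test_voltage_filter_dc_fixed_point(self):
        v = 0.0
        for _ in range(int(300.0 / DT)):
            v = filter_voltage(v, -55.0, theta=-65.0, tau=10.0, dt=DT)
        assert v == pytest.approx(10.0, rel=1e-6)

    def test_voltage_filter_monotone_decay_below_threshold(self):
        vals = []
        v = 3.0
        for _ in range(1000):
            v = filter_voltage(v, -80.0, theta=-65.0, tau=10.0, dt=DT)
            vals.append(v)
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert all(v >= 0 for v in vals)


class TestHill:
    def test_half_activation_at_ka(self):
        assert hill_activation(2.5, Ka=2.5, n=4) == pytest.approx(0.5)

    def test_zero_input_is_zero(self):
        assert hill_activation(0.0, Ka=1.0, n=2, theta_phi=0.3) == 0.0

    def test_saturation_minus_threshold(self):
        assert hill_activation(1e9, Ka=1.0, n=2,
                               theta_phi=0.2) == pytest.approx(0.8, rel=1e-6)

    def test_rectified_when_threshold_exceeds_hill(self):
        assert hill_activation(0.1, Ka=1.0, n=4, theta_phi=0.5) == 0.0

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            hill_activation(-0.1, Ka=1.0, n=2)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_increasing_in_conductance(self, g1, g2):
        if g1 == g2:
            return
        lo, hi = sorted((g1, g2))
        assert hill_activation(lo, 1.0, 2) < hill_activation(hi, 1.0, 2)


class TestMovingThreshold:
    def test_decay_without_drive(self):
        p = get_params("stdp-2c")
        thm, thp = 2.0, 1.0
        for _ in range(int(1000.0 / DT)):
            thm, thp = update_moving_threshold(thm, thp, 0.0, 0.0, p, DT)
        assert thm == pytest.approx(0.0, abs=1e-4)
        assert thp == pytest.approx(0.0, abs=1e-4)

    def test_cross_coupled_fixed_points(self):
        """Sustained LTP activity raises the LTD threshold to b*phi and
        vice versa."""
        p = get_params("stdp-2c")
        thm = thp = 0.0
        for _ in range(int(2000.0 / DT)):
            thm, thp = update_moving_threshold(thm, thp, 0.3, 0.01, p, DT)
        assert thm == pytest.approx(p.b_theta_minus * 0.3, rel=1e-4)
        assert thp == pytest.approx(p.b_theta_plus * 0.01, rel=1e-4)

    def test_matches_closed_form_for_constant_drive(self):
        p = get_params("stdp-2c")
        thm = thp = 0.0
        target = p.b_theta_minus * 0.2
        for i in range(int(300.0 / DT)):
            thm, thp = update_moving_threshold(thm, thp, 0.2, 0.0, p, DT)
            t = (i + 1) * DT
            exact = target * (1.0 - math.exp(-t / p.tau_theta_minus))
            if exact > 1e-9:
                assert abs(thm - exact) / exact < 1e-3


class TestPresynTrace:
    def test_stays_zero_without_spikes(self):
        x = 0.0
        for _ in range(1000):
            x = update_presyn_trace(x, False, 15.0, DT)
        assert x == 0.0

    def test_single_spike_decay(self):
        tau = 15.0
        x = update_presyn_trace(0.0, True, tau, DT)
        for _ in range(int(round(tau / DT)) - 1):
            x = update_presyn_trace(x, False, tau, DT)
        assert x == pytest.approx((1.0 / tau) * math.exp(-1.0), rel=1e-3)

    def test_two_spikes_superpose(self):
        tau, gap = 15.0, 5.0
        x = update_presyn_trace(0.0, True, tau, DT)
        for i in range(1, int(round(3 * tau / DT))):
            x = update_presyn_trace(x, i == int(round(gap / DT)), tau, DT)
        t_end = int(round(3 * tau / DT)) * DT
        exact = (math.exp(-t_end / tau)
                 + math.exp(-(t_end - gap) / tau)) / tau
        assert x == pytest.approx(exact, rel=1e-6)


class TestWeightDynamics:
    def test_soft_bound_at_wmax(self):
        p = get_params("stdp-2c")
        s = PlasticityState(w=p.w_max, phi_plus=1.0, vbar_plus=10.0)
        assert weight_derivative(s, p) == 0.0

    def test_soft_bound_at_wmin(self):
        p = get_params("stdp-2c")
        s = PlasticityState(w=p.w_min, phi_minus=1.0, vbar_minus=10.0,
                            xbar=0.1)
        assert weight_derivative(s, p) == 0.0

    def test_pure_ltd_drive_is_negative(self):
        p = get_params("stdp-2c")
        s = PlasticityState(w=1.0, phi_minus=0.5, vbar_minus=5.0, xbar=0.05)
        assert weight_derivative(s, p) < 0.0

    def test_zero_drive_leaves_state_except_threshold_decay(self):
        p = get_params("stdp-2c")
        s = PlasticityState(w=1.3, theta_phi_minus=1.0)
        s2 = step_plasticity(s, 0.0, 0.0, -70.0, False, p, DT)
        assert s2.w == s.w
        assert s2.gbar_plus == 0.0 and s2.xbar == 0.0
        assert 0.0 < s2.theta_phi_minus < s.theta_phi_minus

    def test_rejects_non_finite_input(self):
        p = get_params("stdp-2c")
        with pytest.raises(ValueError):
            step_plasticity(PlasticityState(), float("nan"), 0.0, -65.0,
                            False, p, DT)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_weight_stays_bounded_under_random_drive(self, seed):
        """w in [w_min, w_max] for arbitrary bounded conductance/voltage
        drive, including drives far stronger than physiological."""
        rng = np.random.default_rng(seed)
        p = get_params("stdp-2c")
        s = PlasticityState(w=float(rng.uniform(p.w_min, p.w_max)))
        for _ in range(400):
            s = step_plasticity(
                s, float(rng.uniform(0, 0.05)), float(rng.uniform(0, 0.05)),
                float(rng.uniform(-90, 40)), bool(rng.random() < 0.05),
                p, 0.1)
            assert p.w_min <= s.w <= p.w_max

    def test_ltp_history_suppresses_subsequent_ltd(self):
        """Competition: an established phi+ history elevates theta_phi- and
        an otherwise LTD-inducing drive depresses strictly less than from a
        cold start."""
        p = get_params("stdp-2c")

        def depress(state):
            # weak GluN2A-dominated drive: activates phi- but not phi+
            for _ in range(int(200.0 / 0.1)):
                state = step_plasticity(state, 3e-4, 0.0, -60.0, True,
                                        p, 0.1)
            return state.w

        cold = PlasticityState(w=1.0)
        # pre-establish strong LTP-pathway activity -> raised LTD threshold
        primed = PlasticityState(w=1.0)
        for _ in range(int(300.0 / 0.1)):
            primed = step_plasticity(primed, 0.0, 0.01, -50.0, False, p, 0.1)
        primed = PlasticityState(w=1.0,
                                 theta_phi_minus=primed.theta_phi_minus)
        assert primed.theta_phi_minus > 0.01
        assert depress(primed) > depress(cold)

    def test_glun2b_silencing_scales_ltp_conductance_by_k2b(self):
        """With g2B zeroed the LTP-pathway drive drops to (1-k2B+) of the
        equal-conductance case (linearity of the subunit mix)."""
        p = get_params("stdp-2c")
        s_full = step_plasticity(PlasticityState(), 1.0, 1.0, -65.0, False,
                                 p, DT)
        s_no2b = step_plasticity(PlasticityState(), 1.0, 0.0, -65.0, False,
                                 p, DT)
        assert s_no2b.gbar_plus == pytest.approx(
            (1.0 - p.k2B_plus) * s_full.gbar_plus, rel=1e-9)


class TestParameterSets:
    def test_three_published_sets_available(self):
        assert set(PARAM_SETS) == {"stdp-2c", "alt-1", "alt-2"}

    def test_override_validation_names_field(self):
        with pytest.raises(ValueError, match="k2B_plus"):
            get_params("stdp-2c", k2B_plus=1.3)

    def test_unknown_set_rejected(self):
        with pytest.raises(KeyError):
            get_params("no-such-set")

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            PlasticityParams(w_min=2.0, w_max=1.0)
        with pytest.raises(ValueError):
            PlasticityParams(tau_delta=0.0)


class TestStandaloneRule:
    def test_rest_trace_leaves_weight_unchanged(self):
        trace = generate_fixture_traces("rest")
        out = run_rule_on_trace(trace)
        assert out.w.iloc[-1] == pytest.approx(1.0)
        assert (out.xbar == 0.0).all()

    def test_doublet_trace_drives_both_pathways(self):
        trace = generate_fixture_traces("doublet-pairing")
        out = run_rule_on_trace(trace)
        assert out.gbar_plus.max() > 0.0
        assert out.gbar_minus.max() > 0.0
        assert out.vbar_plus.max() > 0.0
        assert len(out) == len(trace)

    def test_matches_step_plasticity(self):
        """The vectorized trace runner and the single-step API are the same
        computation."""
        trace = generate_fixture_traces("single-epsp").iloc[:2000]
        out = run_rule_on_trace(trace)
        p = get_params("stdp-2c")
        s = PlasticityState()
        dt = float(trace.time.iloc[1] - trace.time.iloc[0])
        for i in range(len(trace)):
            s = step_plasticity(s, trace.g2A.iloc[i], trace.g2B.iloc[i],
                                trace.V.iloc[i],
                                trace.presyn_spike.iloc[i] > 0, p, dt)
        assert s.w == pytest.approx(out.w.iloc[-1], rel=1e-12)
        assert s.gbar_minus == pytest.approx(out.gbar_minus.iloc[-1],
                                             rel=1e-12)

    def test_rejects_malformed_trace(self):
        with pytest.raises(ValueError, match="missing"):
            run_rule_on_trace(pd.DataFrame({"time": [0, 1], "V": [0, 0]}))
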