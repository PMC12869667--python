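"""Unit dynamics: activation, Euler stepping, rest, traces, WTA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msinet.dynamics import (
    NetworkState,
    activation,
    rest_state,
    simulate,
    step,
)
from msinet.params import NetworkParams
from msinet.stimuli import StimulusEvent


class TestActivation:
    def test_closed_form_logistic_value(self):
        # 1 / (1 + e^-3) for slope 0.3, center 20, u = 30
        p = NetworkParams(act_slope=0.3, act_center=20.0)
        assert activation(30.0, p) == pytest.approx(1 / (1 + math.exp(-3)), abs=1e-12)

    def test_midpoint_is_half_max(self, td_params):
        assert activation(td_params.act_center, td_params) == pytest.approx(0.5)

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, u1, u2):
        p = NetworkParams()
        z1, z2 = activation(u1, p), activation(u2, p)
        assert 0.0 < z1 < p.z_max and 0.0 < z2 < p.z_max
        if u1 <= u2:
            assert z1 <= z2


class TestStep:
    def test_zero_dt_returns_state_unchanged(self, td_params):
        s = NetworkState(u_a=3.0, q_v=0.1, t=7.0)
        s2 = step(s, (1.0, 0.0), td_params, dt=0.0)
        assert s2.u_a == s.u_a and s2.q_v == s.q_v

    def test_leak_fixed_point_is_stationary(self):
        # all weights zero, no input: u = 0 is the exact fixed point
        p = NetworkParams(
            w_ma=0, w_mv=0, w_av=0, w_va=0, w_Ia=0, w_Iv=0,
            l_av=0, l_va=0, l_a=0, l_v=0,
        )
        s = NetworkState()
        for _ in range(20):
            s = step(s, (0.0, 0.0), p, dt=1.0)
        assert s.u_a == 0.0 and s.u_m == 0.0

    def test_matches_first_order_relaxation_oracle(self):
        # single driven unit, all couplings zero: u(t) = I*(1 - e^(-t/tau))
        p = NetworkParams(
            w_ma=0, w_mv=0, w_av=0, w_va=0, w_Ia=0, w_Iv=0,
            l_av=0, l_va=0, l_a=0, l_v=0, i0_a=5.0,
        )
        dt, tau, amp = 0.1, p.tau_fast, p.i0_a
        s = NetworkState()
        for k in range(1, 1201):
            s = step(s, (1.0, 0.0), p, dt=dt)
            exact = amp * (1.0 - math.exp(-k * dt / tau))
            assert s.u_a == pytest.approx(exact, abs=0.01 * amp)

    def test_nonfinite_state_rejected(self, td_params):
        s = NetworkState(u_a=float("nan"))
        with pytest.raises(FloatingPointError):
            step(s, (0.0, 0.0), td_params, dt=1.0)


class TestSimulate:
    def test_rest_stays_below_detector_threshold(self, td_params):
        trace = simulate([], td_params, duration=12000.0)
        assert trace.z.max() < 0.10

    def test_trace_grids_are_consistent(self, td_params):
        tr = simulate([StimulusEvent("A", 100.0)], td_params, duration=500.0)
        assert tr.t.shape[0] == tr.z.shape[0] == tr.q.shape[0] == 501
        assert np.allclose(np.diff(tr.t), tr.dt)

    def test_overlapping_same_channel_events_rejected(self, td_params):
        evs = [StimulusEvent("A", 100.0), StimulusEvent("AV", 130.0)]
        with pytest.raises(ValueError, match="overlap"):
            simulate(evs, td_params, duration=500.0)

    def test_event_outside_window_rejected(self, td_params):
        with pytest.raises(ValueError, match="outside"):
            simulate([StimulusEvent("A", 490.0)], td_params, duration=500.0)

    def test_deterministic_bitwise(self, td_params):
        ev = [StimulusEvent("AV", 200.0)]
        a = simulate(ev, td_params, 1000.0, interneuron_jitter=[(1e-6, 0.0)])
        b = simulate(ev, td_params, 1000.0, interneuron_jitter=[(1e-6, 0.0)])
        assert np.array_equal(a.z, b.z) and np.array_equal(a.q, b.q)

    def test_cross_modal_competition_suppresses_input_units(self, td_params):
        """Immature (inhibitory) coupling: an input unit responds less to
        an audiovisual pulse than to its own modality alone."""
        rest = rest_state(td_params)
        a = simulate([StimulusEvent("A", 500.0)], td_params, 2000.0, initial=rest)
        av = simulate(
            [StimulusEvent("AV", 500.0)], td_params, 2000.0, initial=rest,
            interneuron_jitter=[(1e-6, 0.0)],
        )
        assert av.series("a").max() < a.series("a").max()

    def test_cross_modal_facilitation_in_mature_network(self, adult_params):
        """Excitatory coupling: the same comparison reverses in adults."""
        rest = rest_state(adult_params)
        a = simulate([StimulusEvent("A", 500.0)], adult_params, 2000.0, initial=rest)
        av = simulate(
            [StimulusEvent("AV", 500.0)], adult_params, 2000.0, initial=rest,
            interneuron_jitter=[(1e-6, 0.0)],
        )
        assert av.series("a").max() > a.series("a").max()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_rates_bounded_under_random_drive(self, seed):
        """Firing rates and slow traces stay in [0, z_max] for arbitrary
        bounded stimulation and random (valid) parameter draws."""
        r = np.random.default_rng(seed)
        p = NetworkParams(
            w_ma=r.uniform(0, 20), w_mv=r.uniform(0, 20),
            w_av=r.uniform(-35, 8), w_va=r.uniform(-35, 8),
            w_Ia=r.uniform(0, 200), w_Iv=r.uniform(0, 200),
            l_av=r.uniform(0, 200), l_va=r.uniform(0, 200),
            l_a=r.uniform(0, 80), l_v=r.uniform(0, 80),
        )
        events, t = [], 100.0
        while t < 2800.0:
            events.append(StimulusEvent(("A", "V", "AV")[r.integers(3)], t))
            t += r.uniform(200, 800)
        tr = simulate(events, p, 3000.0,
                      interneuron_jitter=[(1e-6, 0.0)] * len(events))
        assert tr.z.min() >= 0.0 and tr.z.max() <= p.z_max
        assert tr.q.min() >= 0.0 and tr.q.max() <= p.z_max


class TestSlowInhibition:
    def test_trace_persists_across_isi_range(self, td_params):
        """The slow trace raised by a 60 ms visual pulse is still present
        1 s later and decays by 3 s, spanning the task's ISI range."""
        rest = rest_state(td_params)
        tr = simulate([StimulusEvent("V", 500.0)], td_params, 4000.0, initial=rest)
        q0 = rest.q_v
        q1s = tr.q[1500, 1] - q0
        q3s = tr.q[3500, 1] - q0
        assert q1s > q3s > 0.0

    def test_winner_takes_all_single_winner(self, td_params):
        """An audiovisual pulse drives both interneurons symmetrically;
        after settling, the tie-break leaves exactly one active."""
        rest = rest_state(td_params)
        tr = simulate(
            [StimulusEvent("AV", 500.0)], td_params, 1500.0, initial=rest,
            interneuron_jitter=[(1e-6, 0.0)],
        )
        end = 559  # just before pulse offset
        z_Ia, z_Iv = tr.z[end, 3], tr.z[end, 4]
        assert (z_Ia > 0.5) != (z_Iv > 0.5)

    def test_rest_state_is_stationary(self, td_params):
        rest = rest_state(td_params)
        tr = simulate([], td_params, 1000.0, initial=rest)
        assert np.allclose(tr.z[0], tr.z[-1], atol=1e-4)
        assert max(rest.z_a, rest.z_v, rest.z_m, rest.z_Ia, rest.z_Iv) < 0.10
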