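"""Plasticity semantics: closed-form pairings, lazy vs dense integration,
and the shape of the weight-change curve."""

import math

import numpy as np
import pytest

import spikelang as sl
from spikelang.compiler import compile_model
from spikelang.network import Network, SpikeTrainInput


def make_pair_net(lif, stdp, pre_times, post_times, h=0.1, delay=1.0,
                  overrides=None):
    """Two driven neurons joined by one plastic synapse.

    ``pre_times``/``post_times`` are the desired emission stamps; a strong
    input spike one step earlier makes the neuron fire exactly then.
    """
    net = Network(h=h, seed=1)
    pre = net.create(lif, 1, name="pre")
    # the post threshold sits above the transmitted weight (w = 1) so only
    # the strong driving input controls its spike times
    post = net.create(lif, 1, name="post", overrides={"V_theta": (2.5, "mV")})
    net.attach_spike_train(pre, "spikes_in",
                           SpikeTrainInput([t - h for t in pre_times],
                                           weight=5.0))
    net.attach_spike_train(post, "spikes_in",
                           SpikeTrainInput([t - h for t in post_times],
                                           weight=5.0))
    syn = stdp
    if overrides:
        syn = compile_model(sl.load_model_text("stdp_synapse"))
        syn.parameter_defaults.update(overrides)
    g = net.connect(pre, post, [(0, 0)], synapse=syn, weight=1.0, delay=delay,
                    pre_port="pre_spikes", post_ports=["post_spikes"])
    net.record(pre)
    net.record(post)
    return net, g, pre, post


class TestSinglePairClosedForm:
    def test_causal_pair_potentiates_by_exp_kernel(self, lif_model,
                                                   stdp_model):
        """t_post - t_pre = 5 ms, lambda_p = 0.01, tau_p = 20 ms:
        dw = 0.01 * exp(-5/20) ~= 0.0077880."""
        net, g, pre, post = make_pair_net(lif_model, stdp_model,
                                          pre_times=[10.0], post_times=[15.0])
        rec = net.simulate(40.0)
        net.finalize()
        assert list(rec.spikes("pre")[0]) == [10.0]
        assert list(rec.spikes("post")[0]) == [15.0]
        dw = g.weights[0] - 1.0
        expected = 0.01 * math.exp(-5.0 / 20.0)
        assert dw == pytest.approx(expected, rel=1e-12)

    def test_anti_causal_pair_depresses_by_exp_kernel(self, lif_model,
                                                      stdp_model):
        net, g, pre, post = make_pair_net(lif_model, stdp_model,
                                          pre_times=[15.0], post_times=[7.0])
        net.simulate(40.0)
        net.finalize()
        dw = g.weights[0] - 1.0
        expected = -0.01 * math.exp(-8.0 / 20.0)
        assert dw == pytest.approx(expected, rel=1e-12)

    def test_pairing_is_delay_invariant_in_emission_time(self, lif_model,
                                                         stdp_model):
        """The anchor convention pairs emission times, so the measured dw
        does not depend on the transmission delay."""
        results = []
        for delay in (0.5, 2.0, 4.0):
            net, g, _, _ = make_pair_net(lif_model, stdp_model,
                                         pre_times=[10.0], post_times=[15.0],
                                         delay=delay)
            net.simulate(40.0)
            net.finalize()
            results.append(g.weights[0])
        assert results[0] == results[1] == results[2]


class TestWeightChangeCurve:
    def test_sign_structure_and_kernel_magnitudes(self, lif_model, stdp_model):
        """dw(dt) is positive for causal pairings, negative for anti-causal,
        with exponentially decaying magnitude on both branches."""
        dts = [-20.0, -10.0, -4.0, 4.0, 10.0, 20.0]
        dws = []
        for dt in dts:
            t_pre = 30.0
            net, g, _, _ = make_pair_net(lif_model, stdp_model,
                                         pre_times=[t_pre],
                                         post_times=[t_pre + dt])
            net.simulate(80.0)
            net.finalize()
            dws.append(g.weights[0] - 1.0)
        for dt, dw in zip(dts, dws):
            if dt > 0:
                assert dw == pytest.approx(0.01 * math.exp(-dt / 20.0),
                                           rel=1e-12)
            else:
                assert dw == pytest.approx(-0.01 * math.exp(dt / 20.0),
                                           rel=1e-12)


class TestLazyVsDense:
    def test_event_driven_updates_match_dense_grid_integration(self,
                                                               lif_model,
                                                               stdp_model):
        """The lazily updated synapse (analytic reconstruction between
        events) agrees with a dense per-step integration of the trace ODEs
        to 1e-10 on random spike trains."""
        rng = np.random.default_rng(123)
        h, T = 0.1, 5000.0
        pre_times = np.unique(
            np.round(np.sort(rng.uniform(5, T - 50, 60)), 1))
        post_times = np.unique(
            np.round(np.sort(rng.uniform(5, T - 50, 75)), 1))
        # avoid identical stamps across the two trains for a clean oracle
        post_times = post_times[~np.isin(post_times, pre_times)]
        net, g, pre, post = make_pair_net(lif_model, stdp_model,
                                          pre_times=pre_times,
                                          post_times=post_times)
        rec = net.simulate(T)
        net.finalize()
        got_pre = rec.spikes("pre")[0]
        got_post = rec.spikes("post")[0]
        assert np.allclose(got_pre, pre_times)
        assert np.allclose(got_post, post_times)

        # dense oracle: exact per-step decay of both traces on the grid,
        # weight updates applied at the emission stamps
        lam_p = lam_d = 0.01
        tau_p = tau_d = 20.0
        decay_p, decay_d = math.exp(-h / tau_p), math.exp(-h / tau_d)
        pre_steps = set(np.round(got_pre / h).astype(int))
        post_steps = set(np.round(got_post / h).astype(int))
        tr_pre = tr_post = 0.0
        w = 1.0
        for k in range(int(T / h) + 1):
            if k in post_steps:      # postsynaptic handler runs first
                w += lam_p * tr_pre
                tr_post += 1.0
            if k in pre_steps:
                w -= lam_d * tr_post
                tr_pre += 1.0
            tr_pre *= decay_p
            tr_post *= decay_d
        assert g.weights[0] == pytest.approx(w, rel=1e-10)

    def test_trace_state_matches_dense_integration(self, lif_model,
                                                   stdp_model):
        """The synapse's presynaptic trace after a run equals the dense
        integration of its ODE."""
        rng = np.random.default_rng(9)
        h, T = 0.1, 1000.0
        pre_times = np.unique(np.round(np.sort(rng.uniform(5, T - 20, 40)), 1))
        net, g, pre, _ = make_pair_net(lif_model, stdp_model,
                                       pre_times=pre_times, post_times=[])
        rec = net.simulate(T)
        net.finalize()
        stamps = rec.spikes("pre")[0]
        tau_p = 20.0
        t_end = float(g.last_anchor[0])
        dense = sum(math.exp(-(t_end - t) / tau_p) for t in stamps
                    if t <= t_end)
        assert g.syn_state["tr_pre"][0] == pytest.approx(dense, rel=1e-10)
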