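"""Time-driven kernel: populations, connections, devices, determinism."""

import numpy as np
import pytest

import spikelang as sl
from spikelang import units as U
from spikelang.compiler import compile_model
from spikelang.diagnostics import ModelError
from spikelang.network import (FixedIndegree, Network, PoissonInput,
                               SpikeTrainInput, StepCurrent)

COUNTER_SRC = """model counter:
    state:
        n_events real = 0.0
        first_t ms = -1 ms
    input:
        in_port <- spike
    update:
        n_events = n_events + 0.0
    onReceive(in_port):
        n_events += 1.0
        if first_t < 0 ms:
            first_t = t
"""


class TestCreate:
    def test_initial_values_from_declarations(self, adex_model):
        net = Network(h=0.1, seed=1)
        pop = net.create(adex_model, 10)
        assert pop.n == 10
        assert np.all(pop.state["V_m"] == adex_model.parameter_defaults["E_L"])
        assert np.all(pop.state["I_adap"] == 0.0)

    def test_override_with_wrong_dimension_rejected(self, adex_model):
        net = Network(h=0.1, seed=1)
        with pytest.raises(U.UnitError):
            net.create(adex_model, 1, overrides={"C_m": (10.0, "mV")})

    def test_override_scaled_through_conversion_factor(self, adex_model):
        net = Network(h=0.1, seed=1)
        pop = net.create(adex_model, 1, overrides={"C_m": (0.25, "nF")})
        assert pop.params["C_m"] == pytest.approx(250.0, rel=1e-12)  # in pF

    def test_random_initializer_uses_network_rng(self):
        src = ("model m:\n    state:\n"
               "        x real = random_uniform(0.0, 1.0)\n")
        cm = compile_model(src)
        a = Network(h=0.1, seed=5).create(cm, 4).state["x"]
        b = Network(h=0.1, seed=5).create(cm, 4).state["x"]
        c = Network(h=0.1, seed=6).create(cm, 4).state["x"]
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert len(np.unique(a)) == 4


class TestConnect:
    def test_fixed_indegree_samples_distinct_sources(self, lif_model):
        net = Network(h=0.1, seed=1)
        src_pop = net.create(lif_model, 50)
        tgt_pop = net.create(lif_model, 20)
        g = net.connect(src_pop, tgt_pop, FixedIndegree(10), weight=0.1,
                        delay=1.0)
        assert g.m == 200
        for j in range(20):
            sources = g.src[g.tgt == j]
            assert len(sources) == 10
            assert len(np.unique(sources)) == 10  # multapses excluded

    def test_indegree_exceeding_pool_rejected(self, lif_model):
        net = Network(h=0.1, seed=1)
        pop = net.create(lif_model, 5)
        with pytest.raises(ModelError):
            net.connect(pop, pop, FixedIndegree(10), weight=0.1, delay=1.0)

    def test_explicit_single_pair(self, lif_model):
        net = Network(h=0.1, seed=1)
        pop = net.create(lif_model, 3)
        g = net.connect(pop, pop, [(0, 2)], weight=0.1, delay=1.0)
        assert g.m == 1 and g.src[0] == 0 and g.tgt[0] == 2

    def test_same_seed_identical_adjacency(self, lif_model):
        def build(seed):
            net = Network(h=0.1, seed=seed)
            pop = net.create(lif_model, 30)
            g = net.connect(pop, pop, FixedIndegree(7), weight=0.1, delay=1.0)
            return g.src.copy(), g.tgt.copy()

        s1, t1 = build(9)
        s2, t2 = build(9)
        assert np.array_equal(s1, s2) and np.array_equal(t1, t2)

    def test_delay_below_resolution_rejected(self, lif_model):
        net = Network(h=0.1, seed=1)
        pop = net.create(lif_model, 2)
        with pytest.raises(ModelError):
            net.connect(pop, pop, [(0, 1)], weight=0.1, delay=0.05)


class TestSimulate:
    def test_adex_at_rest_stays_silent(self, adex_model):
        net = Network(h=0.1, seed=1)
        pop = net.create(adex_model, 1)
        net.record(pop)
        rec = net.simulate(100.0)
        assert len(rec.spikes(pop.name)[0]) == 0

    def test_step_current_protocol_replays_exactly(self, adex_model):
        def run():
            net = Network(h=0.1, seed=1)
            pop = net.create(adex_model, 1)
            net.attach_current(pop, "I_stim", StepCurrent(800.0, start=25.0))
            net.record(pop, ["V_m"])
            rec = net.simulate(200.0)
            return rec.spikes(pop.name)[0], rec.state(pop.name, "V_m")[1]

        s1, v1 = run()
        s2, v2 = run()
        assert len(s1) > 0
        assert np.array_equal(s1, s2)
        assert np.array_equal(v1, v2)
        # spikes only after stimulus onset; adaptation lengthens intervals
        assert s1[0] > 25.0
        assert np.all(np.diff(np.diff(s1)) > 0)

    def test_threshold_detection_converges_with_resolution(self, adex_model):
        def spikes(h):
            net = Network(h=h, seed=1)
            pop = net.create(adex_model, 1)
            net.attach_current(pop, "I_stim", StepCurrent(800.0, start=25.0))
            net.record(pop)
            return net.simulate(150.0).spikes(pop.name)[0]

        coarse = spikes(0.1)
        fine = spikes(0.05)
        assert len(coarse) == len(fine)
        assert np.max(np.abs(coarse - fine)) <= 0.1 + 1e-9

    def test_every_spike_delivered_once_at_emission_plus_delay(self, lif_model):
        counter = compile_model(COUNTER_SRC)
        net = Network(h=0.1, seed=1)
        src_pop = net.create(lif_model, 1)
        tgt = net.create(counter, 1)
        delay = 2.5
        net.connect(src_pop, tgt, [(0, 0)], weight=1.0, delay=delay)
        net.attach_poisson(src_pop, "spikes_in",
                           PoissonInput(rate=80.0, weight=1.5))
        net.record(src_pop)
        rec = net.simulate(500.0)
        emitted = rec.spikes(src_pop.name)[0]
        # events still in flight at the end are not yet counted
        arrived = emitted[emitted + delay <= 500.0]
        assert len(emitted) > 5
        assert tgt.state["n_events"][0] == len(arrived)
        assert tgt.state["first_t"][0] == pytest.approx(emitted[0] + delay)

    def test_zero_duration_is_a_no_op(self, adex_model):
        net = Network(h=0.1, seed=1)
        pop = net.create(adex_model, 1)
        net.record(pop)
        rec = net.simulate(0.0)
        assert len(rec.spikes(pop.name)[0]) == 0

    def test_simulation_is_bitwise_deterministic(self, adex_model, stdp_model,
                                                 lif_model):
        def run():
            net = Network(h=0.1, seed=77)
            pool = net.create(adex_model, 20)
            drv = net.create(lif_model, 5)
            net.attach_poisson(drv, "spikes_in",
                               PoissonInput(rate=50.0, weight=1.3))
            net.connect(drv, pool, FixedIndegree(3), synapse=stdp_model,
                        weight=-80.0, delay=1.0, pre_port="pre_spikes",
                        post_ports=["post_spikes"])
            net.attach_poisson(pool, "spikes_in",
                               PoissonInput(rate=30000.0, weight=-14.0))
            net.record(pool, ["V_m"])
            rec = net.simulate(300.0)
            return (rec.spikes(pool.name), rec.state(pool.name, "V_m")[1])

        (t1, i1), v1 = run()
        (t2, i2), v2 = run()
        assert np.array_equal(t1, t2) and np.array_equal(i1, i2)
        assert np.array_equal(v1, v2)


class TestGridVsPrecise:
    def find_discrepancy_params(self):
        """Brute-force search for a configuration where the coarse grid
        emits one spike but fine resolution emits none."""
        lif = compile_model(sl.load_model_text("lif_toy"))

        def count(h, w, t1, t2, tau):
            net = Network(h=h, seed=1)
            pop = net.create(lif, 1, overrides={"tau_m": (tau, "ms")})
            net.attach_spike_train(pop, "spikes_in",
                                   SpikeTrainInput([t1, t2], weight=w))
            net.record(pop)
            return len(net.simulate(5.0).spikes(pop.name)[0])

        for w in (0.55, 0.6, 0.7):
            for tau in (0.4, 0.5, 0.7):
                for (t1, t2) in ((0.25, 0.65), (0.15, 0.75)):
                    if count(1.0, w, t1, t2, tau) == 1 and \
                            count(0.05, w, t1, t2, tau) == 0:
                        return w, tau, t1, t2
        raise AssertionError("no discrepancy construction found")

    def test_coarse_grid_emits_fine_grid_does_not(self):
        w, tau, t1, t2 = self.find_discrepancy_params()
        lif = compile_model(sl.load_model_text("lif_toy"))

        def count(h):
            net = Network(h=h, seed=1)
            pop = net.create(lif, 1, overrides={"tau_m": (tau, "ms")})
            net.attach_spike_train(pop, "spikes_in",
                                   SpikeTrainInput([t1, t2], weight=w))
            net.record(pop)
            return len(net.simulate(5.0).spikes(pop.name)[0])

        assert count(1.0) == 1   # both spikes rounded onto one step: fires
        assert count(0.05) == 0  # leak between the separated spikes: silent
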