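"""Co-generation: dependency analysis, pairing transform, renamer."""

import copy

import numpy as np
import pytest

import spikelang as sl
from spikelang import ast_nodes as A
from spikelang.cogeneration import (PairingOptions, analyze_post_dependence,
                                    declared_names, keyword_rename,
                                    pair_compile, pair_transform)
from spikelang.compiler import compile_model
from spikelang.diagnostics import has_errors
from spikelang.network import Network, PoissonInput
from spikelang.validation import check_model


class TestPostDependence:
    def test_stdp_movable_set(self, stdp_ast):
        movable = analyze_post_dependence(stdp_ast, ["post_spikes"])
        assert movable == {"tr_post", "tau_d"}

    def test_no_post_ports_means_nothing_movable(self, stdp_ast):
        assert analyze_post_dependence(stdp_ast, []) == set()

    def test_cross_coupled_trace_not_movable(self):
        # brute-force counterexample: tr_post's dynamics read tr_pre
        src = ("model syn:\n"
               "    state:\n"
               "        w real = 1.0\n"
               "        tr_pre real = 0.0\n"
               "        tr_post real = 0.0\n"
               "    parameters:\n        tau ms = 20 ms\n"
               "    equations:\n"
               "        tr_pre' = -tr_pre / tau\n"
               "        tr_post' = (-tr_post + tr_pre) / tau\n"
               "    input:\n"
               "        pre_spikes <- spike\n"
               "        post_spikes <- spike\n"
               "    output:\n        spike\n"
               "    onReceive(post_spikes):\n        tr_post += 1.0\n"
               "    onReceive(pre_spikes):\n"
               "        tr_pre += 1.0\n        deliver_spike(w)\n")
        movable = analyze_post_dependence(sl.parse_model(src), ["post_spikes"])
        assert "tr_post" not in movable


class TestPairTransform:
    def test_moved_material_lands_in_neuron(self, adex_ast, stdp_ast):
        paired = pair_transform(adex_ast, stdp_ast,
                                PairingOptions("adex_neuron", "stdp_synapse",
                                               ["post_spikes"]))
        neuron_states = {d.name for d in paired.neuron_ast.state.declarations}
        assert "tr_post" in neuron_states
        eq_vars = {i.lhs_variable for i in paired.neuron_ast.equations.items
                   if isinstance(i, A.Equation)}
        assert "tr_post" in eq_vars
        # the jump landed in the spike-emitting condition handler
        cond = paired.neuron_ast.on_condition[0]
        assert any(isinstance(s, A.Assignment) and s.target.name == "tr_post"
                   for s in cond.statements)
        # and the synapse lost it
        syn_states = {d.name for d in paired.synapse_ast.state.declarations}
        assert "tr_post" not in syn_states
        assert "tau_d" not in {d.name for d in
                               paired.synapse_ast.parameters.declarations}

    def test_symbol_conservation(self, adex_ast, stdp_ast):
        before = declared_names(adex_ast) | declared_names(stdp_ast)
        paired = pair_transform(adex_ast, stdp_ast,
                                PairingOptions("adex_neuron", "stdp_synapse",
                                               ["post_spikes"]))
        after = (declared_names(paired.neuron_ast)
                 | declared_names(paired.synapse_ast))
        assert after == before  # no collision, so no rename; nothing lost
        syn_names = declared_names(paired.synapse_ast)
        assert paired.moved_symbols.isdisjoint(syn_names)

    def test_memory_proxy_fewer_synapse_states(self, adex_ast, stdp_ast):
        paired = pair_transform(adex_ast, stdp_ast,
                                PairingOptions("adex_neuron", "stdp_synapse",
                                               ["post_spikes"]))
        assert (len(paired.synapse_ast.state.declarations)
                < len(stdp_ast.state.declarations))

    def test_transformed_pair_revalidates_and_prints(self, adex_ast, stdp_ast):
        paired = pair_transform(adex_ast, stdp_ast,
                                PairingOptions("adex_neuron", "stdp_synapse",
                                               ["post_spikes"]))
        assert not has_errors(check_model(paired.neuron_ast))
        assert not has_errors(check_model(paired.synapse_ast))
        for ast in (paired.neuron_ast, paired.synapse_ast):
            assert sl.parse_model(sl.print_model(ast)) == ast

    def test_name_collision_renames_consistently(self, stdp_ast):
        # a neuron that already owns a variable called tr_post
        src = ("model n:\n"
               "    state:\n        V_m mV = 0 mV\n        tr_post real = 5.0\n"
               "    equations:\n        V_m' = -V_m / (10 ms)\n"
               "    input:\n        in_spikes <- spike\n"
               "    output:\n        spike\n"
               "    update:\n        integrate_odes()\n"
               "    onCondition(V_m >= 1 mV):\n        emit_spike()\n")
        neuron = sl.parse_model(src)
        paired = pair_transform(neuron, stdp_ast,
                                PairingOptions("n", "stdp_synapse",
                                               ["post_spikes"]))
        new_name = paired.renames["tr_post"]
        assert new_name != "tr_post"
        states = {d.name for d in paired.neuron_ast.state.declarations}
        assert {"tr_post", new_name} <= states
        assert not has_errors(check_model(paired.neuron_ast))
        assert not has_errors(check_model(paired.synapse_ast))
        # the synapse accessor references the renamed variable
        printed = sl.print_model(paired.synapse_ast)
        assert f"__post__{new_name}()" in printed

    def test_empty_movable_set_is_identity(self, adex_ast, stdp_ast):
        before_n = copy.deepcopy(adex_ast)
        before_s = copy.deepcopy(stdp_ast)
        paired = pair_transform(adex_ast, stdp_ast,
                                PairingOptions("adex_neuron", "stdp_synapse",
                                               post_ports=[]))
        assert paired.neuron_ast == before_n
        assert paired.synapse_ast == before_s


class TestKeywordRename:
    def test_reserved_name_renamed_everywhere(self):
        # `class` collides with a keyword of a generated target language
        src = ("model m:\n"
               "    state:\n        class real = 0.0\n"
               "    update:\n        class += 1.0\n")
        renamed = keyword_rename(sl.parse_model(src), {"class"})
        printed = sl.print_model(renamed)
        assert "class__v" in printed
        assert "class real" not in printed
        assert sl.parse_model(printed) == renamed

    def test_no_collision_is_identity(self, adex_ast):
        before = copy.deepcopy(adex_ast)
        assert keyword_rename(adex_ast, {"while", "class"}) == before

    def test_suffix_iterated_until_free(self):
        src = ("model m:\n"
               "    state:\n"
               "        auto real = 0.0\n"
               "        auto__v real = 1.0\n")
        renamed = keyword_rename(sl.parse_model(src), {"auto"})
        names = {d.name for d in renamed.state.declarations}
        assert names == {"auto__v__v", "auto__v"}


class TestBehavioralEquivalence:
    def test_paired_weight_trajectory_matches_unpaired(self, lif_text,
                                                       stdp_text):
        """Random Poisson pre/post drive, 10 s: the co-generated pair and the
        untransformed synapse produce the same weight trajectory to 1e-12."""
        lif_ast = sl.parse_model(lif_text)
        stdp_ast = sl.parse_model(stdp_text)
        lif_paired, stdp_paired = pair_compile(
            lif_ast, stdp_ast,
            PairingOptions("lif_toy", "stdp_synapse", ["post_spikes"]))
        lif = compile_model(lif_text)
        stdp = compile_model(stdp_text)

        def run(paired):
            net = Network(h=0.1, seed=2024)
            pre = net.create(lif, 1, name="pre")
            post = net.create(lif_paired if paired else lif, 1, name="post")
            net.attach_poisson(pre, "spikes_in",
                               PoissonInput(rate=30.0, weight=1.2))
            net.attach_poisson(post, "spikes_in",
                               PoissonInput(rate=25.0, weight=1.2))
            g = net.connect(pre, post, [(0, 0)],
                            synapse=stdp_paired if paired else stdp,
                            weight=1.0, delay=1.0, pre_port="pre_spikes",
                            post_ports=["post_spikes"])
            net.record_weights(g, interval=50.0)
            rec = net.simulate(10_000.0)
            net.finalize()
            return rec.weights(g.label)[1].ravel(), g.weights[0]

        w_traj_u, w_final_u = run(False)
        w_traj_p, w_final_p = run(True)
        rel = np.max(np.abs(w_traj_u - w_traj_p)
                     / np.maximum(np.abs(w_traj_u), 1e-30))
        assert rel <= 1e-12
        assert abs(w_final_u - w_final_p) <= 1e-12 * abs(w_final_u)
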