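"""Context conditions: symbol tables and the model-checking battery."""

import pytest

import spikelang as sl
from spikelang.diagnostics import has_errors
from spikelang.symbols import build_symbol_tables
from spikelang.validation import check_model


def errors(diags):
    return [d for d in diags if d.severity == "error"]


class TestSymbolTables:
    def test_fixture_names_all_resolve(self, adex_ast):
        scope, diags = build_symbol_tables(adex_ast)
        assert not diags
        for name in ("V_m", "I_adap", "C_m", "K_syn", "I_syn", "spikes_in",
                     "I_stim"):
            assert scope.lookup(name) is not None

    def test_duplicate_declaration_in_scope(self):
        src = ("model m:\n    state:\n        x real = 0.0\n"
               "        x real = 1.0\n")
        _, diags = build_symbol_tables(sl.parse_model(src))
        assert any(d.code == "duplicate-name" for d in diags)

    def test_predefined_time_symbol(self):
        src = "model m:\n    state:\n        x ms = 0 ms\n"
        scope, _ = build_symbol_tables(sl.parse_model(src))
        t = scope.lookup("t")
        assert t is not None and t.type.quantity.dimension.exponents[2] == 1

    def test_derivative_symbols_registered(self, adex_ast):
        scope, _ = build_symbol_tables(adex_ast)
        vm_dot = scope.lookup("V_m'")
        assert vm_dot is not None and vm_dot.kind == "equation-variable"


class TestCheckModel:
    @pytest.mark.parametrize("fixture", ["adex_neuron", "stdp_synapse",
                                         "lif_toy"])
    def test_fixtures_have_zero_errors(self, fixture):
        diags = check_model(sl.load_model(fixture))
        assert not errors(diags), [str(d) for d in diags]

    def test_check_model_is_idempotent(self, adex_ast):
        first = check_model(adex_ast)
        second = check_model(adex_ast)
        assert [str(d) for d in first] == [str(d) for d in second]

    def test_unit_error_in_update_statement(self):
        src = ("model m:\n"
               "    state:\n        V_m mV = 0 mV\n"
               "    parameters:\n        g_L nS = 30 nS\n"
               "    update:\n        V_m = V_m + g_L\n")
        diags = check_model(sl.parse_model(src))
        assert any(d.code == "unit-mismatch" for d in errors(diags))

    def test_on_receive_for_unknown_port(self):
        src = ("model m:\n"
               "    state:\n        x real = 0.0\n"
               "    input:\n        a <- spike\n"
               "    onReceive(b):\n        x += 1.0\n")
        diags = check_model(sl.parse_model(src))
        assert any(d.code == "unknown-port" for d in errors(diags))

    def test_emit_spike_needs_spike_output(self):
        src = ("model m:\n    state:\n        x real = 0.0\n"
               "    update:\n        emit_spike()\n")
        diags = check_model(sl.parse_model(src))
        assert any(d.code == "no-spike-output" for d in errors(diags))

    def test_integrate_odes_argument_must_be_governed_state(self):
        src = ("model m:\n"
               "    state:\n        x real = 0.0\n        y real = 0.0\n"
               "    equations:\n        x' = -x / (1 ms)\n"
               "    update:\n        integrate_odes(y)\n")
        diags = check_model(sl.parse_model(src))
        assert any(d.code == "integrate-odes-arg" for d in errors(diags))

    def test_equation_lhs_must_be_state(self):
        src = ("model m:\n"
               "    parameters:\n        p real = 1.0\n"
               "    equations:\n        p' = -p / (1 ms)\n")
        diags = check_model(sl.parse_model(src))
        assert any(d.code == "equation-lhs" for d in errors(diags))

    def test_assigning_parameter_is_an_error(self):
        src = ("model m:\n"
               "    parameters:\n        p real = 1.0\n"
               "    update:\n        p = 2.0\n")
        diags = check_model(sl.parse_model(src))
        assert any(d.code == "assign-to-constant" for d in errors(diags))

    def test_condition_must_be_boolean(self):
        src = ("model m:\n    state:\n        x real = 0.0\n"
               "    output:\n        spike\n"
               "    onCondition(x + 1.0):\n        emit_spike()\n")
        diags = check_model(sl.parse_model(src))
        assert any(d.code == "condition-type" for d in errors(diags))

    def test_vector_size_must_be_positive(self):
        src = "model m:\n    state:\n        x real[0] = 0.0\n"
        diags = check_model(sl.parse_model(src))
        assert any(d.code == "vector-size" for d in errors(diags))

    def test_kernel_may_only_depend_on_time_and_parameters(self):
        src = ("model m:\n"
               "    state:\n        x real = 0.0\n"
               "    equations:\n"
               "        kernel K = x * exp(-t / (1 ms))\n"
               "        x' = convolve(K, s) / (1 ms)\n"
               "    input:\n        s <- spike\n")
        diags = check_model(sl.parse_model(src))
        assert any(d.code == "kernel-dependency" for d in errors(diags))

    def test_errors_sorted_before_warnings(self):
        src = ("model m:\n"
               "    state:\n        i integer = 0\n        V_m mV = 0 mV\n"
               "    parameters:\n        g nS = 1 nS\n"
               "    update:\n"
               "        i = 1.5\n"           # warning: real -> integer
               "        V_m = V_m + g\n")    # error: unit mismatch
        diags = check_model(sl.parse_model(src))
        severities = [d.severity for d in diags]
        assert severities == sorted(severities,
                                    key=["error", "warning", "info"].index)
        assert "error" in severities and "warning" in severities
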