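"""Tokenizer, parser, and pretty-printer behavior."""

import pytest

import spikelang as sl
from spikelang import ast_nodes as A
from spikelang.diagnostics import ModelError
from spikelang.lexer import COMMENT, DEDENT, EOF, INDENT, NAME, NEWLINE, OP, tokenize
from spikelang.printer import print_model


class TestTokenize:
    def test_declaration_line_tokens_and_positions(self):
        toks = tokenize("V_m mV = E_L")
        kinds = [(t.type, t.value) for t in toks]
        assert kinds[:4] == [(NAME, "V_m"), (NAME, "mV"), (OP, "="),
                             (NAME, "E_L")]
        assert [(t.line, t.col) for t in toks[:4]] == [(1, 1), (1, 5), (1, 8),
                                                       (1, 10)]

    def test_empty_source_yields_only_end_marker(self):
        toks = tokenize("")
        assert [t.type for t in toks] == [EOF]

    def test_indent_dedent_pairing(self):
        toks = tokenize("a x:\n    b y:\n        c real\n    d real\n")
        types = [t.type for t in toks]
        assert types.count(INDENT) == types.count(DEDENT) == 2
        # every position lies inside the source and tokens appear in order
        positions = [(t.line, t.col) for t in toks if t.type not in
                     (INDENT, DEDENT, NEWLINE, EOF)]
        assert positions == sorted(positions)

    def test_comment_token_captured(self):
        toks = tokenize("x real = 1. # the x var")
        comments = [t for t in toks if t.type == COMMENT]
        assert len(comments) == 1 and comments[0].value == "the x var"

    def test_illegal_character_reports_location(self):
        with pytest.raises(ModelError) as err:
            tokenize("x real = 1 $ 2")
        assert err.value.diagnostic.code == "lex-illegal"
        assert err.value.diagnostic.location == (1, 12)


class TestParse:
    def test_adex_structure(self, adex_ast):
        m = adex_ast
        assert m.name == "adex_neuron"
        assert m.docstring is not None
        assert m.equations is not None
        assert len(m.continuous_ports()) == 1
        assert len(m.spike_ports()) >= 1
        assert m.output is not None and m.output.kind == "spike"
        assert m.update is not None
        assert len(m.on_condition) == 1

    def test_stdp_has_two_event_handlers(self, stdp_ast):
        handlers = stdp_ast.on_receive
        assert len(handlers) == 2
        assert {h.port for h in handlers} == {"pre_spikes", "post_spikes"}
        assert {h.priority for h in handlers} == {1, 2}

    def test_duplicate_singleton_block_rejected(self):
        src = "model m:\n    state:\n        x real = 0.0\n" \
              "    state:\n        y real = 0.0\n"
        with pytest.raises(ModelError) as err:
            sl.parse_model(src)
        assert err.value.diagnostic.code == "duplicate-block"

    def test_syntax_error_carries_location(self):
        with pytest.raises(ModelError) as err:
            sl.parse_model("model m:\n    state:\n        x = = 1\n")
        line, _col = err.value.diagnostic.location
        assert line == 3

    def test_trailing_comment_documents_declaration(self):
        src = "model m:\n    state:\n        x real = 1. # the x var\n"
        m = sl.parse_model(src)
        assert m.state.declarations[0].doc_comment == "the x var"

    def test_equation_order_from_primes(self):
        src = ("model m:\n    state:\n        x real = 0.0\n"
               "    equations:\n        x'' = -x / (1 ms * 1 ms)\n")
        eq = sl.parse_model(src).equations.items[0]
        assert eq.lhs_variable == "x" and eq.order == 2

    def test_parse_is_deterministic(self, adex_text):
        assert sl.parse_model(adex_text) == sl.parse_model(adex_text)


class TestPrintRoundTrip:
    @pytest.mark.parametrize("name", ["adex_neuron", "stdp_synapse", "lif_toy"])
    def test_fixture_round_trip(self, name):
        ast = sl.load_model(name)
        assert sl.parse_model(print_model(ast)) == ast

    def test_priority_annotation_preserved(self, stdp_ast):
        printed = print_model(stdp_ast)
        assert "priority=2" in printed and "priority=1" in printed
        assert sl.parse_model(printed) == stdp_ast

    def test_programmatic_ast_prints_parseable(self):
        model = A.Model(name="tiny", blocks=[
            A.DeclarationsBlock(kind="state", declarations=[
                A.Declaration(name="v", declared_type="mV",
                              initializer=A.NumberLiteral(0.0, unit="mV"))]),
            A.UpdateBlock(statements=[
                A.Assignment(target=A.VarRef(name="v"), op="+=",
                             value=A.NumberLiteral(1.0, unit="mV"))]),
        ])
        assert sl.parse_model(print_model(model)) == model
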