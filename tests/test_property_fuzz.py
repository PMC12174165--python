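"""Property-based fuzzing over small generated models.

Two properties: every generated well-formed AST survives a
print -> parse round trip unchanged, and every model that passes the
context-condition checks can be lowered, instantiated, and simulated
without name or type errors.
"""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st

import spikelang as sl
from spikelang import ast_nodes as A
from spikelang.compiler import compile_model
from spikelang.diagnostics import has_errors
from spikelang.network import Network, PoissonInput
from spikelang.validation import check_model

STATE_NAMES = ["v0", "v1", "v2"]
PARAM_NAMES = ["p0", "p1"]


def num(x):
    return A.NumberLiteral(value=float(x))


def ms(x):
    return A.NumberLiteral(value=float(x), unit="ms")


@st.composite
def linear_rhs(draw, states):
    """-(sum of coeff * state [* state]) / (tau ms): a well-typed real rate.

    Literals stay non-negative: a programmatic negative literal would print
    with a sign and re-parse as a unary minus, which is the expected
    asymmetry, so negativity lives in explicit UnaryOp nodes.
    """
    terms = draw(st.lists(st.sampled_from(states), min_size=1, max_size=3))
    coeffs = [draw(st.floats(0.01, 2.0)) for _ in terms]
    expr = None
    for name, c in zip(terms, coeffs):
        term = A.BinaryOp(op="*", left=num(round(c, 3)),
                          right=A.VarRef(name=name))
        if draw(st.booleans()):
            term = A.BinaryOp(op="*", left=term, right=A.VarRef(name=name))
        expr = term if expr is None else A.BinaryOp(op="+", left=expr,
                                                    right=term)
    tau = draw(st.sampled_from([1.0, 5.0, 20.0]))
    return A.BinaryOp(op="/", left=A.UnaryOp(op="-", operand=expr),
                      right=ms(tau))


@st.composite
def small_models(draw):
    n_states = draw(st.integers(1, 3))
    states = STATE_NAMES[:n_states]
    decls = [A.Declaration(name=s, declared_type="real",
                           initializer=num(round(draw(st.floats(0, 1)), 3)))
             for s in states]
    params = [A.Declaration(name=p, declared_type="real",
                            initializer=num(round(draw(st.floats(0.1, 2)), 3)))
              for p in PARAM_NAMES]
    eq_states = draw(st.lists(st.sampled_from(states), unique=True))
    equations = [A.Equation(lhs_variable=s, order=1,
                            rhs=draw(linear_rhs(states)))
                 for s in eq_states]
    blocks: list[A.Block] = [
        A.DeclarationsBlock(kind="state", declarations=decls),
        A.DeclarationsBlock(kind="parameters", declarations=params),
    ]
    if equations:
        blocks.append(A.EquationsBlock(items=equations))
    blocks.append(A.InputBlock(ports=[A.InputPort(name="in0", kind="spike")]))
    blocks.append(A.OutputBlock(kind="spike"))
    update = [A.ExprStmt(call=A.FunctionCall(name="integrate_odes"))] \
        if equations else []
    if draw(st.booleans()):
        update.append(A.Assignment(
            target=A.VarRef(name=states[0]), op="*=", value=num(0.99)))
    if update:
        blocks.append(A.UpdateBlock(statements=update))
    blocks.append(A.OnReceive(port="in0", statements=[
        A.Assignment(target=A.VarRef(name=states[-1]), op="+=",
                     value=A.BinaryOp(op="*", left=A.VarRef(name="in0"),
                                      right=A.VarRef(name="p0")))]))
    blocks.append(A.OnCondition(
        condition=A.BinaryOp(op=">=", left=A.VarRef(name=states[0]),
                             right=num(draw(st.sampled_from([2.0, 5.0])))),
        statements=[A.ExprStmt(call=A.FunctionCall(name="emit_spike")),
                    A.Assignment(target=A.VarRef(name=states[0]), op="=",
                                 value=num(0.0))]))
    return A.Model(name="fuzz", blocks=blocks)


class TestFuzzedModels:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(small_models())
    def test_print_parse_round_trip(self, model):
        assert sl.parse_model(sl.print_model(model)) == model

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(small_models())
    def test_validated_models_lower_and_simulate(self, model):
        diags = check_model(model)
        errors = [d for d in diags if d.severity == "error"]
        assert not errors, [str(d) for d in errors]
        cm = compile_model(sl.print_model(model))
        net = Network(h=0.1, seed=4)
        pop = net.create(cm, 3)
        net.attach_poisson(pop, "in0", PoissonInput(rate=200.0, weight=1.0))
        net.record(pop)
        net.simulate(5.0)
        for s in cm.state_names:
            assert np.all(np.isfinite(pop.state[s]))
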