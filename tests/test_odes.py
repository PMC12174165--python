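"""Lowering, kernel analysis, solver planning, propagators, RK4."""

import math

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.linalg import expm

import spikelang as sl
from spikelang import ast_nodes as A
from spikelang.compiler import compile_model
from spikelang.diagnostics import ModelError
from spikelang.odes import (T_SYM, build_propagator, kernel_to_ode,
                            reduce_to_first_order, rk4_step)


class TestKernelToOde:
    def test_exponential_kernel_is_first_order(self):
        tau = sp.Symbol("tau")
        coeffs, jumps = kernel_to_ode(sp.exp(-T_SYM / tau))
        assert len(coeffs) == 1
        assert sp.simplify(coeffs[0] - 1 / tau) == 0
        assert jumps == [1]

    def test_alpha_kernel_is_second_order_with_aux_jump(self):
        tau = sp.Symbol("tau")
        k = (sp.E / tau) * T_SYM * sp.exp(-T_SYM / tau)
        coeffs, jumps = kernel_to_ode(k)
        assert len(coeffs) == 2
        assert sp.simplify(coeffs[0] - 1 / tau ** 2) == 0
        assert sp.simplify(coeffs[1] - 2 / tau) == 0
        assert jumps[0] == 0
        assert sp.simplify(jumps[1] - sp.E / tau) == 0

    def test_non_polynomial_exponential_kernel_rejected(self):
        with pytest.raises(ModelError) as err:
            kernel_to_ode(1 / (1 + T_SYM))
        assert err.value.diagnostic.code == "unsupported-kernel"


class TestLowering:
    def test_adex_convolution_states(self, adex_model):
        names = adex_model.system.state_names
        assert "__conv_K_syn_spikes_in" in names
        assert "__conv_K_syn_spikes_in__d1" in names
        jumps = adex_model.system.spike_jumps["spikes_in"]
        assert set(jumps) == {"__conv_K_syn_spikes_in__d1"}
        tau = adex_model.parameter_defaults["tau_syn"]
        vec = adex_model.jump_vector("spikes_in",
                                     adex_model.parameter_defaults)
        assert vec[names.index("__conv_K_syn_spikes_in__d1")] == \
            pytest.approx(math.e / tau, rel=1e-15)

    def test_model_without_convolve_unchanged(self, lif_model):
        assert not lif_model.system.convolutions
        assert lif_model.system.state_names == ["V_m"]

    def test_second_order_equation_companion_form(self):
        eq = A.Equation(lhs_variable="x", order=2,
                        rhs=A.UnaryOp(op="-", operand=A.VarRef(name="x")))
        system = reduce_to_first_order([eq])
        assert system.state_names == ["x", "x'"]
        assert system.derivatives["x"] == sp.Symbol("x'")
        assert system.derivatives["x'"] == -sp.Symbol("x")

    def test_mixed_orders_state_count(self):
        eqs = [A.Equation(lhs_variable="a", order=3, rhs=A.VarRef(name="a")),
               A.Equation(lhs_variable="b", order=1, rhs=A.VarRef(name="b")),
               A.Equation(lhs_variable="c", order=2, rhs=A.VarRef(name="c"))]
        system = reduce_to_first_order(eqs)
        assert len(system.state_names) == 3 + 1 + 2


class TestClassification:
    def test_adex_split(self, adex_model):
        plan = adex_model.plan
        assert set(plan.analytic_states) == {"__conv_K_syn_spikes_in",
                                             "__conv_K_syn_spikes_in__d1"}
        assert set(plan.numeric_states) == {"V_m", "I_adap"}

    def test_pure_decay_fully_analytic(self, stdp_model):
        assert set(stdp_model.plan.analytic_states) == {"tr_pre", "tr_post"}
        assert not stdp_model.plan.numeric_states

    def test_nonlinearity_forces_numeric(self):
        src = ("model m:\n    state:\n        v real = 1.0\n"
               "    equations:\n        v' = -(v * v) / (1 ms)\n")
        cm = compile_model(src)
        assert cm.plan.numeric_states == ["v"]
        assert not cm.plan.analytic_states


class TestPropagator:
    def test_scalar_decay(self):
        m = sp.Matrix([[sp.Rational(-1, 1) / sp.Symbol("tau")]])
        p = build_propagator(m, h=1.0, param_values={"tau": 10.0})
        assert p.matrix[0, 0] == pytest.approx(math.exp(-0.1), rel=1e-15)

    def test_alpha_subsystem_closed_form(self):
        # y' = -y/tau + z, z' = -z/tau  ->  P = [[e, h e], [0, e]], e=exp(-h/tau)
        tau, h = 2.0, 0.1
        m = sp.Matrix([[-1 / sp.Symbol("tau"), 1],
                       [0, -1 / sp.Symbol("tau")]])
        p = build_propagator(m, h, {"tau": tau})
        e = math.exp(-h / tau)
        expected = np.array([[e, h * e], [0.0, e]])
        assert np.allclose(p.matrix, expected, rtol=1e-12, atol=1e-15)

    def test_zero_step_is_identity(self):
        m = sp.Matrix([[-0.3, 0.1], [0.0, -0.5]])
        p = build_propagator(m, 0.0)
        assert np.array_equal(p.matrix, np.eye(2))

    def test_affine_offset_against_matrix_exponential(self):
        a = sp.Matrix([[-0.5]])
        b = sp.Matrix([[2.0]])
        p = build_propagator(a, 0.7, offset=b)
        # closed form: x(h) = e^{ah} x0 + (e^{ah} - 1)/a * b
        assert p.matrix[0, 0] == pytest.approx(math.exp(-0.35), rel=1e-14)
        assert p.offset[0] == pytest.approx(
            (math.exp(-0.35) - 1) / (-0.5) * 2.0, rel=1e-12)

    def test_matches_adaptive_oracle_on_random_systems(self):
        """Propagator trajectories track a high-accuracy adaptive integration
        to <= 1e-9 relative error over 100 steps."""
        rng = np.random.default_rng(42)
        h = 0.05
        for _ in range(5):
            n = rng.integers(2, 5)
            a = rng.normal(scale=1.0, size=(n, n))
            a -= (np.abs(a).sum(axis=1) + 0.5) * np.eye(n)  # keep it stable
            x0 = rng.normal(size=n)
            m = sp.Matrix(a)
            p = build_propagator(m, h)
            x = x0.copy()
            for _ in range(100):
                x = p.matrix @ x
            sol = solve_ivp(lambda t, y: a @ y, (0.0, 100 * h), x0,
                            rtol=1e-12, atol=1e-14, method="DOP853")
            ref = sol.y[:, -1]
            assert np.max(np.abs(x - ref)) <= 1e-9 * max(1.0,
                                                         np.max(np.abs(ref)))

    def test_composition_law(self):
        """P(h1) P(h2) == P(h1 + h2) to 1e-12."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.normal(scale=0.5, size=(3, 3))
            m = sp.Matrix(a)
            h1, h2 = rng.uniform(0.01, 0.5, 2)
            p1 = build_propagator(m, float(h1)).matrix
            p2 = build_propagator(m, float(h2)).matrix
            p12 = build_propagator(m, float(h1 + h2)).matrix
            assert np.allclose(p1 @ p2, p12, rtol=1e-12, atol=1e-13)

    def test_propagator_equals_matrix_exponential(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 4))
        p = build_propagator(sp.Matrix(a), 0.3)
        assert np.allclose(p.matrix, expm(a * 0.3), rtol=1e-12, atol=1e-14)


class TestRK4:
    def test_exponential_decay_accuracy(self):
        tau, h = 10.0, 0.1
        y = rk4_step(lambda t, y: -y / tau, 0.0, np.array([1.0]), h)
        assert abs(y[0] - math.exp(-h / tau)) <= 1e-6 * math.exp(-h / tau)

    def test_zero_field_leaves_state(self):
        y = rk4_step(lambda t, y: 0.0 * y, 0.0, np.array([2.5, -1.0]), 0.7)
        assert np.array_equal(y, np.array([2.5, -1.0]))

    def test_constant_derivative_exact(self):
        y = rk4_step(lambda t, y: np.ones_like(y), 0.0, np.array([0.0]), 0.3)
        assert y[0] == pytest.approx(0.3, rel=1e-15)

    def test_substeps_improve_accuracy(self):
        f = lambda t, y: -y
        exact = math.exp(-1.0)
        e1 = abs(rk4_step(f, 0, np.array([1.0]), 1.0, 1)[0] - exact)
        e4 = abs(rk4_step(f, 0, np.array([1.0]), 1.0, 4)[0] - exact)
        assert e4 < e1 / 100


class TestSerialization:
    def test_plan_serializes_to_json(self, adex_model):
        import json
        from spikelang.odes import serialize_plan
        doc = json.loads(serialize_plan(adex_model.system, adex_model.plan))
        assert set(doc) == {"system", "solver_plan"}
        assert doc["solver_plan"]["numeric"] == ["V_m", "I_adap"]
        assert "V_m" in doc["system"]["derivatives"]
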