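"""Lowering of model dynamics to a first-order system and solver planning.

Three transformations happen here:

* convolution lowering -- every ``convolve(K, port)`` occurrence is replaced
  by a fresh state variable.  A kernel of polynomial-times-exponential form
  satisfies a linear constant-coefficient ODE; the convolution of that kernel
  with a Dirac-delta spike train then satisfies the same ODE with per-spike
  jumps equal to the kernel derivatives at 0+.  An exponential kernel yields
  one state (jump 1); the alpha kernel ``(e/tau) t exp(-t/tau)`` yields two
  (value jump 0, auxiliary jump e/tau).

* order reduction -- an order-n equation on x becomes the companion chain
  x, x', ..., x^(n-1).

* solver planning -- the maximal subset of states whose derivatives are
  linear with constant coefficients, and closed under dependency, is solved
  exactly with a propagator matrix P = expm(A h) (the matrix exponential of
  the subsystem matrix); everything else is stepped with classical
  fixed-step RK4.  The analytic part may drive the numeric part, never the
  other way around.

All time-valued symbols are in milliseconds: state magnitudes live in their
declared units, derivatives in (declared unit)/ms, with decadic prefix
mismatches already folded in as numeric factors by the type checker.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import sympy as sp
from scipy.linalg import expm

from . import ast_nodes as A
from .diagnostics import error
from .symbols import INLINE, KERNEL, SymbolTable

T_SYM = sp.Symbol("t")

_MAX_KERNEL_ORDER = 6

_FUNC_MAP = {
    "exp": sp.exp,
    "ln": sp.log,
    "log10": lambda x: sp.log(x, 10),
    "sqrt": sp.sqrt,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "erf": sp.erf,
    "ceil": sp.ceiling,
    "floor": sp.floor,
    "abs": sp.Abs,
    "min": sp.Min,
    "max": sp.Max,
}


def to_sympy(expr: A.Expression, convolution_name: Optional[Callable] = None,
             inline_map: Optional[dict] = None) -> sp.Expr:
    """Convert a type-checked expression AST to a sympy expression.

    Implicit unit-conversion factors recorded by the type checker are folded
    in as numeric multipliers.  ``convolution_name(kernel, port)`` supplies
    the replacement symbol name for convolve() occurrences; ``inline_map``
    maps inline-expression names to (sympy expr, factor) for expansion.
    """
    f = lambda e: to_sympy(e, convolution_name, inline_map)
    if isinstance(expr, A.NumberLiteral):
        return sp.Float(expr.value) if not expr.is_int else sp.Integer(int(expr.value))
    if isinstance(expr, A.BooleanLiteral):
        return sp.true if expr.value else sp.false
    if isinstance(expr, A.VarRef):
        if expr.is_unit_literal:
            return sp.Integer(1)
        if expr.name == "e" and getattr(expr.symbol, "kind", None) == "predefined":
            return sp.E
        if inline_map is not None and expr.name in inline_map:
            inner, factor = inline_map[expr.name]
            return factor * inner if factor != 1.0 else inner
        if expr.index is not None:
            raise error("lower-vector",
                        "vector element references are not supported inside "
                        "equations", expr.span)
        return sp.Symbol(expr.name)
    if isinstance(expr, A.UnaryOp):
        if expr.op == "-":
            return -f(expr.operand)
        if expr.op == "+":
            return f(expr.operand)
        raise error("lower-bool", "boolean operators are not supported in equations",
                    expr.span)
    if isinstance(expr, A.BinaryOp):
        lhs = f(expr.left)
        rhs = f(expr.right)
        if expr.factor_left != 1.0:
            lhs = sp.Float(expr.factor_left) * lhs
        if expr.factor_right != 1.0:
            rhs = sp.Float(expr.factor_right) * rhs
        op = expr.op
        if op == "+":
            return lhs + rhs
        if op == "-":
            return lhs - rhs
        if op == "*":
            return lhs * rhs
        if op == "/":
            return lhs / rhs
        if op == "**":
            return lhs ** rhs
        if op in ("<", "<=", ">", ">=", "==", "!="):
            return sp.Rel(lhs, rhs, op)
        raise error("lower-bool",
                    f"operator {op!r} is not supported in equations", expr.span)
    if isinstance(expr, A.FunctionCall):
        if expr.name.startswith("random_"):
            raise error("lower-random",
                        "random functions are not allowed in equations", expr.span)
        if expr.name not in _FUNC_MAP:
            raise error("lower-call",
                        f"function {expr.name!r} cannot be used in equations",
                        expr.span)
        args = [f(a) for a in expr.args]
        if expr.arg_factors:
            args = [sp.Float(k) * a if k != 1.0 else a
                    for k, a in zip(expr.arg_factors, args)]
        return _FUNC_MAP[expr.name](*args)
    if isinstance(expr, A.Convolve):
        if convolution_name is None:
            raise error("lower-convolve",
                        "convolve() is not allowed in this context", expr.span)
        return sp.Symbol(convolution_name(expr.kernel, expr.port))
    raise TypeError(f"cannot lower {type(expr).__name__}")


# -- kernel analysis --------------------------------------------------------

def kernel_to_ode(kernel_expr: sp.Expr) -> tuple[list[sp.Expr], list[sp.Expr]]:
    """Find the minimal linear constant-coefficient ODE annihilating a kernel.

    Returns ``(coeffs, jumps)`` where ``coeffs = [c_0, ..., c_{n-1}]`` satisfy
    K^(n) + sum_i c_i K^(i) = 0 identically in t, and ``jumps[i] = K^(i)(0+)``.
    Coefficients may depend symbolically on model parameters.  Raises for
    kernels outside the polynomial-times-exponential class.
    """
    derivs = [sp.expand(kernel_expr)]
    for n in range(1, _MAX_KERNEL_ORDER + 1):
        derivs.append(sp.expand(sp.diff(derivs[-1], T_SYM)))
        cs = sp.symbols(f"__c0:{n}")
        candidate = derivs[n] + sum(c * d for c, d in zip(cs, derivs[:n]))
        sol = _solve_identity(candidate, list(cs))
        if sol is not None:
            coeffs = [sp.simplify(sol[c]) for c in cs]
            jumps = [sp.simplify(sp.limit(d, T_SYM, 0, "+")) for d in derivs[:n]]
            return coeffs, jumps
    raise error("unsupported-kernel",
                "kernel is not reducible to a linear constant-coefficient ODE "
                "(polynomial-times-exponential form required)")


def _solve_identity(expr: sp.Expr, unknowns: list[sp.Symbol]) -> Optional[dict]:
    """Solve ``expr == 0`` identically in t for the unknown coefficients."""
    expanded = sp.expand(expr)
    # replace each distinct exponential-in-t atom by a fresh symbol so the
    # identity becomes polynomial in (t, E_1, E_2, ...)
    exp_atoms = sorted(
        (a for a in expanded.atoms(sp.exp) if T_SYM in a.free_symbols),
        key=sp.default_sort_key)
    markers = {a: sp.Symbol(f"__E{i}") for i, a in enumerate(exp_atoms)}
    poly_expr = expanded.subs(markers, simultaneous=True)
    gens = [T_SYM] + list(markers.values())
    try:
        poly = sp.Poly(poly_expr, *gens)
    except sp.PolynomialError:
        return None
    equations = [sp.expand(c) for c in poly.coeffs()]
    if not unknowns:
        return {} if all(eq == 0 for eq in equations) else None
    try:
        sol = sp.linsolve(equations, unknowns)
    except Exception:
        return None
    if not sol or sol is sp.EmptySet:
        return None
    values = next(iter(sol))
    result = dict(zip(unknowns, values))
    # reject underdetermined solutions that still contain the unknowns
    for v in result.values():
        if any(u in v.free_symbols for u in unknowns):
            return None
    return result


# -- the lowered system -----------------------------------------------------

@dataclass
class ConvolutionInfo:
    kernel: str
    port: str
    state_names: list[str]          # value state first, then auxiliaries
    jumps: list[sp.Expr]            # per-unit-weight jump of each state


@dataclass
class FirstOrderSystem:
    """A validated model's dynamics as x' = f(t, x) plus event-driven jumps."""

    state_names: list[str] = field(default_factory=list)
    derivatives: dict[str, sp.Expr] = field(default_factory=dict)
    # spike port -> {state name -> per-unit-weight increment}
    spike_jumps: dict[str, dict[str, sp.Expr]] = field(default_factory=dict)
    initial_values: dict[str, sp.Expr] = field(default_factory=dict)
    convolutions: list[ConvolutionInfo] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "state_names": list(self.state_names),
            "derivatives": {k: str(v) for k, v in self.derivatives.items()},
            "spike_jumps": {p: {k: str(v) for k, v in jumps.items()}
                            for p, jumps in self.spike_jumps.items()},
            "initial_values": {k: str(v) for k, v in self.initial_values.items()},
        }


@dataclass
class SolverPlan:
    """Partition of the state into an exactly solvable part and the rest."""

    analytic_states: list[str] = field(default_factory=list)
    numeric_states: list[str] = field(default_factory=list)
    # for the analytic part: x' = A x + b with constant (parameter) entries
    matrix: Optional[sp.Matrix] = None
    offset: Optional[sp.Matrix] = None
    method: str = "rk4"
    substeps: int = 1

    def to_json(self) -> dict:
        return {
            "analytic": list(self.analytic_states),
            "numeric": list(self.numeric_states),
            "matrix": ([[str(e) for e in row] for row in self.matrix.tolist()]
                       if self.matrix is not None else None),
            "offset": ([str(e) for e in self.offset] if self.offset is not None
                       else None),
            "method": self.method,
            "substeps": self.substeps,
        }


def conv_state_name(kernel: str, port: str, order: int = 0) -> str:
    base = f"__conv_{kernel}_{port}"
    return base if order == 0 else f"{base}__d{order}"


def lower_model(model: A.Model, scope: SymbolTable) -> FirstOrderSystem:
    """Lower a validated model's equations block to a first-order system.

    Inline expressions are expanded, convolve() occurrences become fresh
    states with spike jumps, and higher-order equations become companion
    chains.  Models without an equations block yield an empty system.
    """
    system = FirstOrderSystem()
    eq_block = model.equations
    if eq_block is None:
        return system

    kernels = {item.name: item for item in eq_block.items
               if isinstance(item, A.KernelDef)}
    conv_pairs: dict[tuple[str, str], ConvolutionInfo] = {}

    def conv_name(kernel: str, port: str) -> str:
        key = (kernel, port)
        if key not in conv_pairs:
            kdef = kernels.get(kernel)
            if kdef is None:
                raise error("unknown-kernel", f"kernel {kernel!r} is not defined")
            kexpr = to_sympy(kdef.expression)
            coeffs, jumps = kernel_to_ode(kexpr)
            names = [conv_state_name(kernel, port, i) for i in range(len(coeffs))]
            conv_pairs[key] = ConvolutionInfo(kernel, port, names, jumps)
            # companion chain: y_i' = y_{i+1}; y_{n-1}' = -sum c_i y_i
            for i, name in enumerate(names[:-1]):
                system.derivatives[name] = sp.Symbol(names[i + 1])
            system.derivatives[names[-1]] = -sum(
                c * sp.Symbol(n) for c, n in zip(coeffs, names))
            for name in names:
                system.initial_values[name] = sp.Integer(0)
            jump_map = system.spike_jumps.setdefault(port, {})
            for name, j in zip(names, jumps):
                if j != 0:
                    jump_map[name] = jump_map.get(name, sp.Integer(0)) + j
        return conv_pairs[key].state_names[0]

    # expand inline expressions (in declaration order, so inlines may
    # reference earlier inlines)
    inline_map: dict[str, tuple[sp.Expr, float]] = {}
    for item in eq_block.items:
        if isinstance(item, A.InlineDef):
            inline_map[item.name] = (
                to_sympy(item.expression, conv_name, inline_map),
                item.conv_factor if item.conv_factor else 1.0)

    for item in eq_block.items:
        if not isinstance(item, A.Equation):
            continue
        rhs = to_sympy(item.rhs, conv_name, inline_map)
        if item.rhs_factor != 1.0:
            rhs = sp.Float(item.rhs_factor) * rhs
        base = item.lhs_variable
        if item.order == 1:
            system.derivatives[base] = rhs
        else:
            chain = [base] + [base + "'" * k for k in range(1, item.order)]
            for lo, hi in zip(chain[:-1], chain[1:]):
                system.derivatives[lo] = sp.Symbol(hi)
            system.derivatives[chain[-1]] = rhs
        # initial values of the base state come from its declaration; the
        # chain members default to 0 unless declared
        sym = scope.lookup(base)
        decl = getattr(sym, "node", None)
        if isinstance(decl, A.Declaration) and decl.initializer is not None:
            init = to_sympy(decl.initializer, conv_name, inline_map)
            if decl.init_factor != 1.0:
                init = sp.Float(decl.init_factor) * init
            system.initial_values[base] = init
        else:
            system.initial_values.setdefault(base, sp.Integer(0))
        if item.order > 1:
            for extra in chain[1:]:
                system.initial_values.setdefault(extra, sp.Integer(0))

    system.convolutions = list(conv_pairs.values())
    # deterministic state ordering: equation states in declaration order,
    # then convolution states in creation order
    ordered: list[str] = []
    for name in system.derivatives:
        if name not in ordered:
            ordered.append(name)
    system.state_names = ordered
    return system


def reduce_to_first_order(equations: list[A.Equation]) -> FirstOrderSystem:
    """Order reduction alone (no convolutions, no initial values).

    Convenience entry point used for equation sets outside a full model.
    """
    system = FirstOrderSystem()
    for eq in equations:
        rhs = to_sympy(eq.rhs)
        base = eq.lhs_variable
        chain = [base] + [base + "'" * k for k in range(1, eq.order)]
        for lo, hi in zip(chain[:-1], chain[1:]):
            system.derivatives[lo] = sp.Symbol(hi)
        system.derivatives[chain[-1]] = rhs
    system.state_names = list(system.derivatives)
    return system


# -- solver planning --------------------------------------------------------

def classify(system: FirstOrderSystem,
             parameter_names: set[str],
             forbidden_inputs: Optional[set[str]] = None) -> SolverPlan:
    """Split the state into the maximal exactly solvable subsystem + the rest.

    A state is an analytic candidate if its derivative is affine in the
    states with coefficients (and offset) built from parameters only -- no
    dependence on t or on continuous inputs.  The candidate set is then
    shrunk to its largest subset closed under dependency: an analytic state
    may not be driven by a numeric state.
    """
    forbidden = set(forbidden_inputs or ())
    states = list(system.state_names)
    state_syms = {name: sp.Symbol(name) for name in states}
    candidates: set[str] = set()
    coeff_rows: dict[str, dict[str, sp.Expr]] = {}
    offsets: dict[str, sp.Expr] = {}

    for name in states:
        f = sp.expand(system.derivatives[name])
        row: dict[str, sp.Expr] = {}
        ok = True
        rest = f
        for other in states:
            s = state_syms[other]
            coeff = sp.diff(f, s)
            if coeff.has(*state_syms.values()) if state_syms else False:
                ok = False
                break
            if any(str(fs) in forbidden or fs == T_SYM
                   for fs in coeff.free_symbols):
                ok = False
                break
            if not _params_only(coeff, parameter_names):
                ok = False
                break
            row[other] = coeff
            rest = rest - coeff * s
        if not ok:
            continue
        rest = sp.expand(rest)
        if rest.has(*state_syms.values()) if state_syms else False:
            continue
        if any(str(fs) in forbidden or fs == T_SYM for fs in rest.free_symbols):
            continue
        if not _params_only(rest, parameter_names):
            continue
        candidates.add(name)
        coeff_rows[name] = row
        offsets[name] = rest

    # closure: drop candidates coupled to non-candidates
    changed = True
    while changed:
        changed = False
        for name in list(candidates):
            for other, coeff in coeff_rows[name].items():
                if coeff != 0 and other not in candidates:
                    candidates.discard(name)
                    changed = True
                    break

    analytic = [s for s in states if s in candidates]
    numeric = [s for s in states if s not in candidates]
    plan = SolverPlan(analytic_states=analytic, numeric_states=numeric)
    if analytic:
        n = len(analytic)
        plan.matrix = sp.Matrix(n, n, lambda i, j: coeff_rows[analytic[i]].get(
            analytic[j], sp.Integer(0)))
        plan.offset = sp.Matrix(n, 1, lambda i, _: offsets[analytic[i]])
    return plan


def _params_only(expr: sp.Expr, parameter_names: set[str]) -> bool:
    return all(str(s) in parameter_names for s in expr.free_symbols)


# -- propagators ------------------------------------------------------------

@dataclass
class Propagator:
    """Exact one-step update x(t+h) = P x(t) + q for a linear subsystem."""

    step: float  # h in ms
    matrix: np.ndarray  # n x n
    offset: np.ndarray  # length n; zero for homogeneous systems

    def apply(self, x: np.ndarray) -> np.ndarray:
        return x @ self.matrix.T + self.offset


def build_propagator(matrix: sp.Matrix, h: float,
                     param_values: Optional[dict[str, float]] = None,
                     offset: Optional[sp.Matrix] = None) -> Propagator:
    """Materialize the propagator P = expm(A h) for an analytic subsystem.

    Affine systems x' = A x + b are handled through the augmented matrix
    [[A, b], [0, 0]], which also covers the singular-A case exactly.
    Parameter symbols in A and b are substituted from ``param_values``.
    """
    subs = {sp.Symbol(k): v for k, v in (param_values or {}).items()}
    a_num = np.array(matrix.subs(subs).evalf().tolist(), dtype=float)
    n = a_num.shape[0]
    if not np.all(np.isfinite(a_num)):
        raise error("propagator-nonfinite",
                    "non-finite entries in the subsystem matrix")
    b_num = np.zeros(n)
    if offset is not None:
        b_num = np.array(offset.subs(subs).evalf().tolist(), dtype=float).reshape(n)
    if np.any(b_num != 0.0):
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = a_num
        aug[:n, n] = b_num
        p_aug = expm(aug * h)
        p = p_aug[:n, :n]
        q = p_aug[:n, n]
    else:
        p = expm(a_num * h)
        q = np.zeros(n)
    if not np.all(np.isfinite(p)):
        raise error("propagator-nonfinite", "non-finite propagator entries")
    return Propagator(step=h, matrix=p, offset=q)


# -- numeric stepping -------------------------------------------------------

def rk4_step(f: Callable[[float, np.ndarray], np.ndarray], t: float,
             y: np.ndarray, h: float, substeps: int = 1) -> np.ndarray:
    """Classical 4th-order Runge-Kutta over one step of length h.

    ``substeps`` splits h into equal internal steps; inputs held constant by
    the caller over h are treated as frozen throughout.
    """
    dt = h / substeps
    for k in range(substeps):
        tk = t + k * dt
        k1 = f(tk, y)
        k2 = f(tk + dt / 2.0, y + dt / 2.0 * k1)
        k3 = f(tk + dt / 2.0, y + dt / 2.0 * k2)
        k4 = f(tk + dt, y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return y


def serialize_plan(system: FirstOrderSystem, plan: SolverPlan) -> str:
    """The lowered system + solver plan as a JSON document."""
    return json.dumps({"system": system.to_json(), "solver_plan": plan.to_json()},
                      indent=2)
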