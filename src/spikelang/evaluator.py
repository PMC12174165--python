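"""Numpy-backed evaluation of expressions and imperative statement blocks.

Evaluation is vectorized over model instances: every variable is a numpy
array of shape (n,) (scalars broadcast), and conditional statements are
executed under boolean masks, so one code path serves a single neuron and a
population alike.  Implicit unit-conversion factors recorded by the type
checker are applied during evaluation, which is what makes mixed-prefix
expressions numerically correct.

``while`` loops iterate until the condition mask is everywhere false;
``for`` loops require bounds that are identical across the active instances.
"""

from __future__ import annotations

import numpy as np

from . import ast_nodes as A
from .diagnostics import error
from .symbols import EULER_E


class EvalEnv:
    """Mutable variable namespace plus the callbacks the engine provides."""

    def __init__(self, values: dict, n: int, rng=None, t: float = 0.0,
                 emit_spike=None, deliver_spike=None, integrate_odes=None,
                 accessors: dict | None = None, functions: dict | None = None):
        self.values = values
        self.n = n
        self.rng = rng
        self.t = t
        self.emit_spike = emit_spike
        self.deliver_spike = deliver_spike
        self.integrate_odes = integrate_odes
        self.accessors = accessors or {}  # co-generation post accessors
        self.functions = functions or {}  # user-defined model functions


def _as_array(value, n: int):
    arr = np.asarray(value, dtype=float)
    return arr


def eval_expr(expr: A.Expression, env: EvalEnv, mask=None):
    """Evaluate an expression to a numpy array (or scalar) over instances."""
    if isinstance(expr, A.NumberLiteral):
        return expr.value
    if isinstance(expr, A.BooleanLiteral):
        return expr.value
    if isinstance(expr, A.StringLiteral):
        return expr.value
    if isinstance(expr, A.VarRef):
        return _eval_varref(expr, env, mask)
    if isinstance(expr, A.UnaryOp):
        v = eval_expr(expr.operand, env, mask)
        if expr.op == "-":
            return -v
        if expr.op == "+":
            return +v
        return np.logical_not(v)
    if isinstance(expr, A.BinaryOp):
        return _eval_binary(expr, env, mask)
    if isinstance(expr, A.FunctionCall):
        return _eval_call(expr, env, mask)
    if isinstance(expr, A.Convolve):
        raise error("eval-convolve",
                    "convolve() must be lowered before execution", expr.span)
    raise TypeError(f"cannot evaluate {type(expr).__name__}")


def _eval_varref(expr: A.VarRef, env: EvalEnv, mask):
    if expr.is_unit_literal:
        return 1.0
    name = expr.name
    if name == "t" and name not in env.values:
        return env.t
    if name == "e" and name not in env.values:
        return EULER_E
    if name not in env.values:
        raise error("eval-name", f"name {name!r} has no value", expr.span)
    v = env.values[name]
    if expr.index is not None:
        idx = eval_expr(expr.index, env, mask)
        idx = int(idx) if np.isscalar(idx) or np.ndim(idx) == 0 else idx.astype(int)
        v = np.asarray(v)
        if v.ndim == 2:  # (n, size) per-instance vectors
            return v[np.arange(v.shape[0]), idx] if np.ndim(idx) else v[:, idx]
        return v[idx]
    return v


def _eval_binary(expr: A.BinaryOp, env: EvalEnv, mask):
    left = eval_expr(expr.left, env, mask)
    right = eval_expr(expr.right, env, mask)
    if expr.op in ("and", "or"):
        return (np.logical_and(left, right) if expr.op == "and"
                else np.logical_or(left, right))
    if expr.factor_left != 1.0:
        left = left * expr.factor_left
    if expr.factor_right != 1.0:
        right = right * expr.factor_right
    op = expr.op
    if op == "+":
        return left + right
    if op == "-":
        return left - right
    if op == "*":
        return left * right
    if op == "/":
        if (expr.left.type is not None and expr.right.type is not None
                and expr.left.type.kind == "integer"
                and expr.right.type.kind == "integer"):
            return np.asarray(left, dtype=float) / right
        return left / right
    if op == "**":
        return left ** right
    if op == "==":
        return left == right
    if op == "!=":
        return left != right
    if op == "<":
        return left < right
    if op == "<=":
        return left <= right
    if op == ">":
        return left > right
    if op == ">=":
        return left >= right
    raise ValueError(f"unknown operator {op!r}")


def _broadcast_size(env: EvalEnv, mask):
    if mask is not None:
        return int(np.count_nonzero(mask)) if mask.dtype == bool else len(mask)
    return env.n


def _eval_call(expr: A.FunctionCall, env: EvalEnv, mask):
    name = expr.name
    if name.startswith("__post__"):
        accessor = env.accessors.get(name)
        if accessor is None:
            raise error("eval-accessor",
                        f"no postsynaptic accessor bound for {name!r}", expr.span)
        return accessor(mask)
    args = [eval_expr(a, env, mask) for a in expr.args]
    if expr.arg_factors:
        args = [a * f if f != 1.0 else a for a, f in zip(args, expr.arg_factors)]
    if name == "emit_spike":
        if env.emit_spike is None:
            raise error("eval-emit", "emit_spike() is not available here", expr.span)
        env.emit_spike(mask)
        return None
    if name == "deliver_spike":
        if env.deliver_spike is None:
            raise error("eval-deliver", "deliver_spike() is not available here",
                        expr.span)
        env.deliver_spike(args[0], mask)
        return None
    if name == "integrate_odes":
        if env.integrate_odes is None:
            raise error("eval-integrate",
                        "integrate_odes() is not available here", expr.span)
        env.integrate_odes([a.name for a in expr.args])
        return None
    if name in _MATH:
        return _MATH[name](*args)
    if name == "random_normal":
        return args[0] + args[1] * env.rng.standard_normal(_broadcast_size(env, mask))
    if name == "random_uniform":
        lo, hi = args
        return lo + (hi - lo) * env.rng.random(_broadcast_size(env, mask))
    if name == "random_poisson":
        return env.rng.poisson(args[0], _broadcast_size(env, mask)).astype(float)
    fn = env.functions.get(name)
    if fn is not None:
        return fn(args, env, mask)
    raise error("eval-call", f"function {name!r} is not executable", expr.span)


_MATH = {
    "exp": np.exp, "ln": np.log, "log10": np.log10, "sqrt": np.sqrt,
    "sin": np.sin, "cos": np.cos, "tan": np.tan,
    "erf": None,  # bound below to avoid importing scipy at module import cost
    "ceil": np.ceil, "floor": np.floor, "abs": np.abs,
    "min": np.minimum, "max": np.maximum,
}


def _erf(x):
    from scipy.special import erf
    return erf(x)


_MATH["erf"] = _erf


def _assign_masked(values: dict, name: str, new, mask, n: int):
    """Write ``new`` into values[name] under the active mask."""
    if mask is None:
        values[name] = new
        return
    cur = values[name]
    if not isinstance(cur, np.ndarray):
        cur = np.broadcast_to(np.asarray(cur, dtype=float), (n,)).copy()
        values[name] = cur
    v = np.asarray(new)
    cur[mask] = v[mask] if v.ndim and v.shape == mask.shape else new


def exec_statements(stmts: list[A.Statement], env: EvalEnv, mask=None) -> object:
    """Execute a statement list under an optional boolean mask.

    Returns a return-value array when a ``return`` statement runs (function
    bodies), else None.  With a mask, assignments touch only the active
    instances; nested ifs refine the mask.
    """
    for s in stmts:
        if isinstance(s, A.Assignment):
            _exec_assignment(s, env, mask)
        elif isinstance(s, A.DeclarationStmt):
            d = s.declaration
            if d.initializer is not None:
                v = eval_expr(d.initializer, env, mask)
                if d.init_factor != 1.0:
                    v = v * d.init_factor
            else:
                v = 0.0
            if mask is None:
                env.values[d.name] = v
            else:
                env.values.setdefault(d.name, np.zeros(env.n))
                _assign_masked(env.values, d.name, v, mask, env.n)
        elif isinstance(s, A.ExprStmt):
            eval_expr(s.call, env, mask)
        elif isinstance(s, A.ReturnStmt):
            if s.value is None:
                return None
            v = eval_expr(s.value, env, mask)
            if s.conv_factor != 1.0:
                v = v * s.conv_factor
            return v
        elif isinstance(s, A.IfStmt):
            _exec_if(s, env, mask)
        elif isinstance(s, A.WhileStmt):
            _exec_while(s, env, mask)
        elif isinstance(s, A.ForStmt):
            _exec_for(s, env, mask)
        else:
            raise TypeError(f"cannot execute {type(s).__name__}")
    return None


def _exec_assignment(s: A.Assignment, env: EvalEnv, mask):
    value = eval_expr(s.value, env, mask)
    if s.conv_factor != 1.0:
        value = value * s.conv_factor
    name = s.target.name
    if name not in env.values:
        raise error("eval-name", f"assignment to unknown name {name!r}", s.span)
    cur = env.values[name]
    if s.target.index is not None:
        idx = int(eval_expr(s.target.index, env, mask))
        arr = np.asarray(cur)
        target_slice = (slice(None), idx) if arr.ndim == 2 else idx
        if s.op == "=":
            arr[target_slice] = value
        elif s.op == "+=":
            arr[target_slice] += value
        elif s.op == "-=":
            arr[target_slice] -= value
        elif s.op == "*=":
            arr[target_slice] *= value
        elif s.op == "/=":
            arr[target_slice] /= value
        return
    if mask is None:
        if s.op == "=":
            if isinstance(cur, np.ndarray):
                cur[...] = value
            else:
                env.values[name] = value if np.ndim(value) else float(value)
        elif isinstance(cur, np.ndarray):
            if s.op == "+=":
                cur += value
            elif s.op == "-=":
                cur -= value
            elif s.op == "*=":
                cur *= value
            elif s.op == "/=":
                cur /= value
        else:
            ops = {"+=": lambda a, b: a + b, "-=": lambda a, b: a - b,
                   "*=": lambda a, b: a * b, "/=": lambda a, b: a / b}
            env.values[name] = ops[s.op](cur, value)
        return
    if not isinstance(cur, np.ndarray):
        cur = np.broadcast_to(np.asarray(cur, dtype=float), (env.n,)).copy()
        env.values[name] = cur
    v = np.asarray(value)
    picked = v[mask] if v.ndim and v.shape == mask.shape else v
    if s.op == "=":
        cur[mask] = picked
    elif s.op == "+=":
        cur[mask] += picked
    elif s.op == "-=":
        cur[mask] -= picked
    elif s.op == "*=":
        cur[mask] *= picked
    elif s.op == "/=":
        cur[mask] /= picked


def _cond_mask(cond_value, mask, n: int):
    c = np.asarray(cond_value)
    if c.ndim == 0:
        c = np.full(n, bool(c))
    return c if mask is None else np.logical_and(c, mask)


def _exec_if(s: A.IfStmt, env: EvalEnv, mask):
    remaining = (mask if mask is not None else np.ones(env.n, dtype=bool)).copy()
    for cond, body in s.branches:
        if cond is None:
            active = remaining
        else:
            # evaluate the condition once, before the branch body can
            # modify any variable it references
            c = _cond_mask(eval_expr(cond, env, mask), None, env.n)
            active = np.logical_and(remaining, c)
            remaining = np.logical_and(remaining, np.logical_not(c))
        if active.any():
            exec_statements(body, env, active)
        if cond is None or not remaining.any():
            break


def _exec_while(s: A.WhileStmt, env: EvalEnv, mask):
    base = mask if mask is not None else np.ones(env.n, dtype=bool)
    guard = 0
    while True:
        c = _cond_mask(eval_expr(s.condition, env, None), None, env.n)
        active = np.logical_and(base, c)
        if not active.any():
            break
        exec_statements(s.body, env, active)
        guard += 1
        if guard > 10_000_000:
            raise error("eval-while", "while loop exceeded the iteration guard",
                        s.span)


def _exec_for(s: A.ForStmt, env: EvalEnv, mask):
    start = eval_expr(s.start, env, mask)
    stop = eval_expr(s.stop, env, mask)
    step = eval_expr(s.step, env, mask) if s.step is not None else 1
    for v in (np.unique(np.asarray(x)) for x in (start, stop, step)):
        if v.size > 1:
            raise error("eval-for",
                        "for-loop bounds must be identical across instances",
                        s.span)
    i = float(np.asarray(start).flat[0])
    stop_v = float(np.asarray(stop).flat[0])
    step_v = float(np.asarray(step).flat[0])
    while (i < stop_v) if step_v > 0 else (i > stop_v):
        env.values[s.var] = i
        exec_statements(s.body, env, mask)
        i += step_v
    env.values.pop(s.var, None)
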