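"""Runtime API for emitted model code.

The ``generate`` stage can render each compiled model as standalone Python
source.  That source is ordinary code written against this module: masked
assignment, the spike/integration hooks, and the math functions whose numpy
spelling differs from the modeling language's.  The primitives here are the
very ones the tree-walking interpreter uses, so an emitted model reproduces
the interpreted path bit for bit.
"""

from __future__ import annotations

import numpy as np

from .evaluator import EvalEnv, _MATH  # shared semantics by construction

erf = _MATH["erf"]


def assign(env: EvalEnv, name: str, value, mask, op: str = "=") -> None:
    """Masked (compound) assignment into the environment, matching the
    interpreter's write semantics."""
    cur = env.values[name]
    if mask is None:
        if op == "=":
            if isinstance(cur, np.ndarray):
                cur[...] = value
            else:
                env.values[name] = value if np.ndim(value) else float(value)
        elif isinstance(cur, np.ndarray):
            if op == "+=":
                cur += value
            elif op == "-=":
                cur -= value
            elif op == "*=":
                cur *= value
            elif op == "/=":
                cur /= value
        else:
            ops = {"+=": lambda a, b: a + b, "-=": lambda a, b: a - b,
                   "*=": lambda a, b: a * b, "/=": lambda a, b: a / b}
            env.values[name] = ops[op](cur, value)
        return
    if not isinstance(cur, np.ndarray):
        cur = np.broadcast_to(np.asarray(cur, dtype=float), (env.n,)).copy()
        env.values[name] = cur
    v = np.asarray(value)
    picked = v[mask] if v.ndim and v.shape == mask.shape else value
    if op == "=":
        cur[mask] = picked
    elif op == "+=":
        cur[mask] += picked
    elif op == "-=":
        cur[mask] -= picked
    elif op == "*=":
        cur[mask] *= picked
    elif op == "/=":
        cur[mask] /= picked


def declare(env: EvalEnv, name: str, value, mask) -> None:
    if mask is None:
        env.values[name] = value
    else:
        env.values.setdefault(name, np.zeros(env.n))
        assign(env, name, value, mask, "=")


def get(env: EvalEnv, name: str):
    if name in env.values:
        return env.values[name]
    if name == "t":
        return env.t
    if name == "e":
        return np.e
    raise KeyError(name)


def emit_spike(env: EvalEnv, mask) -> None:
    env.emit_spike(mask)


def deliver_spike(env: EvalEnv, value, mask) -> None:
    env.deliver_spike(value, mask)


def integrate_odes(env: EvalEnv, names: list[str]) -> None:
    env.integrate_odes(names)


def accessor(env: EvalEnv, name: str, mask):
    return env.accessors[name](mask)


def _size(env: EvalEnv, mask) -> int:
    if mask is not None:
        return int(np.count_nonzero(mask)) if mask.dtype == bool else len(mask)
    return env.n


def random_normal(env: EvalEnv, mask, mean, std):
    return mean + std * env.rng.standard_normal(_size(env, mask))


def random_uniform(env: EvalEnv, mask, lo, hi):
    return lo + (hi - lo) * env.rng.random(_size(env, mask))


def random_poisson(env: EvalEnv, mask, lam):
    return env.rng.poisson(lam, _size(env, mask)).astype(float)


def cond_mask(env: EvalEnv, value, mask):
    c = np.asarray(value)
    if c.ndim == 0:
        c = np.full(env.n, bool(c))
    return c if mask is None else np.logical_and(c, mask)
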