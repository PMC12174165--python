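"""Emission of compiled models as standalone Python source.

``emit_python`` renders a compiled model's imperative parts -- the update
block, the onCondition handlers, and the onReceive handlers -- as plain
Python functions written against the documented runtime API
(:mod:`spikelang.runtime`).  The emitted operations mirror the tree-walking
interpreter primitive for primitive, so loading the module with
``load_emitted`` and simulating produces bitwise-identical recordings to the
interpreted path.  The continuous dynamics need no emission: the lowered
system and solver plan already execute through the propagator/RK4 machinery.
"""

from __future__ import annotations

import types
from typing import Optional

from . import ast_nodes as A
from .compiler import CompiledModel
from .diagnostics import error

_MATH_SRC = {
    "exp": "np.exp", "ln": "np.log", "log10": "np.log10", "sqrt": "np.sqrt",
    "sin": "np.sin", "cos": "np.cos", "tan": "np.tan", "erf": "rt.erf",
    "ceil": "np.ceil", "floor": "np.floor", "abs": "np.abs",
    "min": "np.minimum", "max": "np.maximum",
}


class _Emitter:
    def __init__(self):
        self.lines: list[str] = []
        self.counter = 0

    def fresh(self, stem: str) -> str:
        self.counter += 1
        return f"_{stem}{self.counter}"

    # -- expressions ---------------------------------------------------------

    def expr(self, e: A.Expression) -> str:
        if isinstance(e, A.NumberLiteral):
            return repr(e.value)
        if isinstance(e, A.BooleanLiteral):
            return "True" if e.value else "False"
        if isinstance(e, A.StringLiteral):
            return repr(e.value)
        if isinstance(e, A.VarRef):
            if e.is_unit_literal:
                return "1.0"
            if e.index is not None:
                raise error("emit-vector",
                            "vector element access is not supported in "
                            "emitted code")
            return f"rt.get(env, {e.name!r})"
        if isinstance(e, A.UnaryOp):
            if e.op == "not":
                return f"np.logical_not({self.expr(e.operand)})"
            return f"({e.op}{self.expr(e.operand)})"
        if isinstance(e, A.BinaryOp):
            left = self.expr(e.left)
            right = self.expr(e.right)
            if e.factor_left != 1.0:
                left = f"({left} * {e.factor_left!r})"
            if e.factor_right != 1.0:
                right = f"({right} * {e.factor_right!r})"
            if e.op == "and":
                return f"np.logical_and({left}, {right})"
            if e.op == "or":
                return f"np.logical_or({left}, {right})"
            if (e.op == "/" and e.left.type is not None
                    and e.right.type is not None
                    and e.left.type.kind == "integer"
                    and e.right.type.kind == "integer"):
                return f"(np.asarray({left}, dtype=float) / {right})"
            return f"({left} {e.op} {right})"
        if isinstance(e, A.FunctionCall):
            return self.call(e)
        raise error("emit-node",
                    f"cannot emit {type(e).__name__} (lower the model first)")

    def call(self, e: A.FunctionCall) -> str:
        args = [self.expr(a) for a in e.args]
        if e.arg_factors:
            args = [f"({a} * {f!r})" if f != 1.0 else a
                    for a, f in zip(args, e.arg_factors)]
        name = e.name
        if name.startswith("__post__"):
            return f"rt.accessor(env, {name!r}, mask)"
        if name == "emit_spike":
            return "rt.emit_spike(env, mask)"
        if name == "deliver_spike":
            return f"rt.deliver_spike(env, {args[0]}, mask)"
        if name == "integrate_odes":
            names = [a.name for a in e.args]
            return f"rt.integrate_odes(env, {names!r})"
        if name in _MATH_SRC:
            return f"{_MATH_SRC[name]}({', '.join(args)})"
        if name.startswith("random_"):
            return f"rt.{name}(env, mask, {', '.join(args)})"
        return f"env.functions[{name!r}]([{', '.join(args)}], env, mask)"

    # -- statements ------------------------------------------------------------

    def stmts(self, body: list[A.Statement], indent: str) -> None:
        if not body:
            self.lines.append(f"{indent}pass")
        for s in body:
            self.stmt(s, indent)

    def stmt(self, s: A.Statement, ind: str) -> None:
        if isinstance(s, A.Assignment):
            if s.target.index is not None:
                raise error("emit-vector",
                            "vector element assignment is not supported in "
                            "emitted code")
            value = self.expr(s.value)
            if s.conv_factor != 1.0:
                value = f"({value} * {s.conv_factor!r})"
            self.lines.append(
                f"{ind}rt.assign(env, {s.target.name!r}, {value}, mask, {s.op!r})")
        elif isinstance(s, A.DeclarationStmt):
            d = s.declaration
            if d.initializer is not None:
                v = self.expr(d.initializer)
                if d.init_factor != 1.0:
                    v = f"({v} * {d.init_factor!r})"
            else:
                v = "0.0"
            self.lines.append(f"{ind}rt.declare(env, {d.name!r}, {v}, mask)")
        elif isinstance(s, A.ExprStmt):
            self.lines.append(f"{ind}{self.call(s.call)}")
        elif isinstance(s, A.ReturnStmt):
            if s.value is None:
                self.lines.append(f"{ind}return None")
            else:
                v = self.expr(s.value)
                if s.conv_factor != 1.0:
                    v = f"({v} * {s.conv_factor!r})"
                self.lines.append(f"{ind}return {v}")
        elif isinstance(s, A.IfStmt):
            rem = self.fresh("rem")
            self.lines.append(
                f"{ind}{rem} = (mask if mask is not None else "
                "np.ones(env.n, dtype=bool)).copy()")
            for cond, body in s.branches:
                if cond is None:
                    self.lines.append(f"{ind}if {rem}.any():")
                    self._masked_block(body, ind + "    ", rem)
                    break
                c = self.fresh("c")
                act = self.fresh("act")
                self.lines.append(
                    f"{ind}{c} = rt.cond_mask(env, {self.expr(cond)}, None)")
                self.lines.append(
                    f"{ind}{act} = np.logical_and({rem}, {c})")
                self.lines.append(
                    f"{ind}{rem} = np.logical_and({rem}, np.logical_not({c}))")
                self.lines.append(f"{ind}if {act}.any():")
                self._masked_block(body, ind + "    ", act)
        elif isinstance(s, A.WhileStmt):
            base = self.fresh("base")
            act = self.fresh("act")
            self.lines.append(
                f"{ind}{base} = (mask if mask is not None else "
                "np.ones(env.n, dtype=bool))")
            self.lines.append(f"{ind}while True:")
            self.lines.append(
                f"{ind}    {act} = np.logical_and({base}, "
                f"rt.cond_mask(env, {self.expr(s.condition)}, None))")
            self.lines.append(f"{ind}    if not {act}.any(): break")
            self._masked_block(s.body, ind + "    ", act)
        elif isinstance(s, A.ForStmt):
            i = self.fresh("i")
            stop = self.fresh("stop")
            step = self.fresh("step")
            self.lines.append(
                f"{ind}{i} = float(np.asarray({self.expr(s.start)}).flat[0])")
            self.lines.append(
                f"{ind}{stop} = float(np.asarray({self.expr(s.stop)}).flat[0])")
            step_src = self.expr(s.step) if s.step is not None else "1.0"
            self.lines.append(
                f"{ind}{step} = float(np.asarray({step_src}).flat[0])")
            self.lines.append(
                f"{ind}while ({i} < {stop}) if {step} > 0 else ({i} > {stop}):")
            self.lines.append(f"{ind}    env.values[{s.var!r}] = {i}")
            self.stmts(s.body, ind + "    ")
            self.lines.append(f"{ind}    {i} += {step}")
            self.lines.append(f"{ind}env.values.pop({s.var!r}, None)")
        else:
            raise error("emit-node", f"cannot emit {type(s).__name__}")

    def _masked_block(self, body: list[A.Statement], ind: str, mask_var: str):
        # re-enter with the refined mask bound to the local name `mask`
        fn = self.fresh("blk")
        saved = self.lines
        self.lines = []
        self.stmts(body, "    ")
        block_lines = self.lines
        self.lines = saved
        self.lines.append(f"{ind}def {fn}(env, mask):")
        for ln in block_lines:
            self.lines.append(ind + ln)
        self.lines.append(f"{ind}{fn}(env, {mask_var})")


def emit_python(model: CompiledModel) -> str:
    """Render the model's imperative parts as Python source text."""
    em = _Emitter()
    out = em.lines
    out.append(f'"""Generated simulation code for model {model.name!r}."""')
    out.append("import numpy as np")
    out.append("from spikelang import runtime as rt")
    out.append("")
    out.append(f"MODEL_NAME = {model.name!r}")
    out.append("")
    if model.update_statements:
        out.append("def UPDATE(env, mask=None):")
        em.stmts(model.update_statements, "    ")
    else:
        out.append("UPDATE = None")
    out.append("")
    cond_names = []
    for i, cond in enumerate(model.conditions):
        cname, bname = f"_cond_{i}", f"_cond_body_{i}"
        out.append(f"def {cname}(env, mask=None):")
        out.append(f"    return {em.expr(cond.condition)}")
        out.append(f"def {bname}(env, mask=None):")
        em.stmts(cond.statements, "    ")
        cond_names.append((cname, bname))
        out.append("")
    out.append("CONDITIONS = [" + ", ".join(f"({c}, {b})" for c, b in cond_names)
               + "]")
    out.append("")
    handler_map: dict[str, list[str]] = {}
    for i, h in enumerate(model.handlers):
        hname = f"_on_{h.port}_{i}"
        out.append(f"def {hname}(env, mask=None):")
        em.stmts(h.statements, "    ")
        out.append("")
        handler_map.setdefault(h.port, []).append(hname)
    out.append("HANDLERS = {" + ", ".join(
        f"{p!r}: [{', '.join(fns)}]" for p, fns in handler_map.items()) + "}")
    out.append("")
    return "\n".join(out)


def load_emitted(model: CompiledModel, source: Optional[str] = None) -> None:
    """Compile emitted source and attach it; the kernel then runs it in
    place of the interpreter."""
    src = source if source is not None else emit_python(model)
    mod = types.ModuleType(f"spikelang_generated_{model.name}")
    exec(compile(src, f"<generated {model.name}>", "exec"), mod.__dict__)
    model.exec_module = mod


def unload_emitted(model: CompiledModel) -> None:
    model.exec_module = None
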