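"""Context conditions: the ordered battery of model-correctness checks.

The checks run in two stages.  Context-dependent syntactic checks: unique
names, event handlers naming real spike ports, convolve arguments, vector
sizes, integrate_odes arguments, emit_spike only in spiking models.  Semantic
checks: full type inference over every expression, initializer/declaration
consistency, equation left-hand sides being state variables, condition
expressions being boolean.  All findings are returned as diagnostics (errors
first); nothing raises, so a model author sees every problem at once.
"""

from __future__ import annotations

from typing import Optional

from . import ast_nodes as A
from . import units as U
from .diagnostics import Diagnostic, has_errors
from .symbols import (EQUATION_VAR, INPUT_PORT, INTERNAL, KERNEL, LOCAL,
                      PARAMETER, PREDEFINED, STATE, Symbol, SymbolTable,
                      build_symbol_tables)
from .typecheck import TypeChecker

_SEVERITY_ORDER = {"error": 0, "warning": 1, "info": 2}


class ModelChecker:
    def __init__(self, model: A.Model):
        self.model = model
        self.diagnostics: list[Diagnostic] = []
        self.scope: Optional[SymbolTable] = None
        self.types = TypeChecker(self.diagnostics)
        self.has_spike_output = (model.output is not None
                                 and model.output.kind == "spike")
        self.equation_vars: set[str] = set()

    def _error(self, code: str, msg: str, node) -> None:
        self.diagnostics.append(Diagnostic("error", code, msg,
                                           getattr(node, "span", None)))

    # -- stage 1: symbols and structural context conditions ------------------

    def run(self) -> list[Diagnostic]:
        self.scope, diags = build_symbol_tables(self.model)
        self.diagnostics.extend(diags)
        self._check_structure()
        self._check_semantics()
        self.diagnostics.sort(key=lambda d: _SEVERITY_ORDER.get(d.severity, 3))
        return self.diagnostics

    def _check_structure(self) -> None:
        model = self.model
        spike_ports = {p.name for p in model.spike_ports()}

        for handler in model.on_receive:
            if handler.port not in spike_ports:
                self._error("unknown-port",
                            f"onReceive names {handler.port!r}, which is not a "
                            "spike input port", handler)

        eq_block = model.equations
        if eq_block is not None:
            seen_lhs: set[str] = set()
            for item in eq_block.items:
                if isinstance(item, A.Equation):
                    sym = self.scope.lookup(item.lhs_variable)
                    if sym is None or sym.kind != STATE:
                        self._error("equation-lhs",
                                    f"equation left-hand side {item.lhs_variable!r} "
                                    "must be a state variable", item)
                    if item.lhs_variable in seen_lhs:
                        self._error("duplicate-equation",
                                    f"multiple equations define {item.lhs_variable!r}",
                                    item)
                    seen_lhs.add(item.lhs_variable)
                    self.equation_vars.add(item.lhs_variable)
                elif isinstance(item, A.KernelDef):
                    self._check_kernel_refs(item)

        for block in model.blocks:
            if isinstance(block, A.DeclarationsBlock):
                for d in block.declarations:
                    self._check_vector_size(d)

    def _check_kernel_refs(self, kernel: A.KernelDef) -> None:
        """Kernels are pure functions of t and constant parameters."""
        for node in A.walk(kernel.expression):
            if isinstance(node, A.VarRef):
                sym = self.scope.lookup(node.name)
                if sym is None:
                    continue  # unit literal or unresolved; typed later
                if sym.kind not in (PARAMETER, INTERNAL, PREDEFINED):
                    self._error("kernel-dependency",
                                f"kernel {kernel.name!r} may depend only on t and "
                                f"parameters, not on {node.name!r} ({sym.kind})",
                                node)
            elif isinstance(node, A.Convolve):
                self._error("kernel-dependency",
                            f"kernel {kernel.name!r} must not contain convolve()",
                            node)

    def _check_vector_size(self, d: A.Declaration) -> None:
        if d.size is None:
            return
        if isinstance(d.size, int):
            if d.size <= 0:
                self._error("vector-size",
                            f"vector {d.name!r} must have a positive size, "
                            f"got {d.size}", d)
        else:
            sym = self.scope.lookup(d.size)
            if sym is None or sym.kind not in (PARAMETER, INTERNAL):
                self._error("vector-size",
                            f"vector size {d.size!r} must name a parameter or "
                            "internal", d)
            elif sym.type is not None and sym.type.kind != "integer":
                self._error("vector-size",
                            f"vector size {d.size!r} must be integer-typed, "
                            f"got {sym.type}", d)

    # -- stage 2: semantic checks (type inference everywhere) ----------------

    def _check_semantics(self) -> None:
        model = self.model
        for block in model.blocks:
            if isinstance(block, A.DeclarationsBlock):
                for d in block.declarations:
                    self._check_declaration(d, self.scope)
            elif isinstance(block, A.EquationsBlock):
                for item in block.items:
                    if isinstance(item, A.Equation):
                        self._check_equation(item)
                    elif isinstance(item, A.InlineDef):
                        t = self.types.infer(item.expression, self.scope)
                        if item.resolved_type is not None:
                            item.conv_factor = self.types.coerce(
                                t, item.resolved_type, item)
                    elif isinstance(item, A.KernelDef):
                        kscope = self.scope.child(f"kernel {item.name}")
                        self.types.infer(item.expression, kscope)
            elif isinstance(block, A.UpdateBlock):
                scope = self.scope.child("update")
                self._check_statements(block.statements, scope, None)
            elif isinstance(block, A.OnReceive):
                scope = self.scope.child(f"onReceive {block.port}")
                self._check_statements(block.statements, scope, None)
            elif isinstance(block, A.OnCondition):
                scope = self.scope.child("onCondition")
                cond_t = self.types.infer(block.condition, scope)
                if cond_t.kind != "boolean":
                    self._error("condition-type",
                                f"onCondition expression must be boolean, got "
                                f"{cond_t}", block.condition)
                self._check_statements(block.statements, scope, None)
            elif isinstance(block, A.FunctionDef):
                scope = self.scope.child(f"function {block.name}")
                for (pname, ptype) in block.params:
                    try:
                        ptd = U.parse_type(ptype)
                    except U.UnitError:
                        ptd = None  # diagnosed during symbol construction
                    diag = scope.define(Symbol(pname, LOCAL, ptd))
                    if diag:
                        self.diagnostics.append(diag)
                ret = None
                if block.return_type:
                    try:
                        ret = U.parse_type(block.return_type)
                    except U.UnitError:
                        ret = None
                self._check_statements(block.statements, scope, ret or U.VOID)

    def _check_declaration(self, d: A.Declaration, scope: SymbolTable) -> None:
        if d.initializer is None:
            return
        t = self.types.infer(d.initializer, scope)
        if d.resolved_type is not None:
            d.init_factor = self.types.coerce(t, d.resolved_type, d)

    def _check_equation(self, eq: A.Equation) -> None:
        rhs_t = self.types.infer(eq.rhs, self.scope)
        sym = self.scope.lookup(eq.lhs_variable)
        if sym is None or sym.type is None:
            return
        if sym.type.kind == "quantity":
            target = U.quantity(sym.type.quantity / (U.MS ** eq.order))
        else:
            # a real state: the derivative carries 1/ms per order
            target = U.quantity(U.QuantityType(U.DIMENSIONLESS, 0) / (U.MS ** eq.order))
            if rhs_t.kind in ("real", "integer"):
                self.diagnostics.append(Diagnostic(
                    "warning", "rate-unit",
                    f"derivative of real state {eq.lhs_variable!r} given as a "
                    "plain number; interpreted as per millisecond", eq.span))
                eq.rhs_factor = 1.0
                return
        eq.rhs_factor = self.types.coerce(rhs_t, target, eq)

    # -- statements ----------------------------------------------------------

    def _check_statements(self, stmts: list[A.Statement], scope: SymbolTable,
                          return_type: Optional[U.TypeDesc]) -> None:
        for s in stmts:
            self._check_statement(s, scope, return_type)

    def _check_statement(self, s: A.Statement, scope: SymbolTable,
                         return_type: Optional[U.TypeDesc]) -> None:
        if isinstance(s, A.DeclarationStmt):
            d = s.declaration
            try:
                d.resolved_type = U.parse_type(d.declared_type)
            except U.UnitError as exc:
                self.diagnostics.append(Diagnostic("error", "unknown-type",
                                                   str(exc), d.span))
                d.resolved_type = None
            # locals become visible only from their declaration onward
            self._check_declaration(d, scope)
            diag = scope.define(Symbol(d.name, LOCAL, d.resolved_type, d,
                                       vector_size=d.size))
            if diag:
                self.diagnostics.append(diag)
        elif isinstance(s, A.Assignment):
            self._check_assignment(s, scope)
        elif isinstance(s, A.ExprStmt):
            self._check_call_statement(s, scope)
        elif isinstance(s, A.ReturnStmt):
            if return_type is None:
                self._error("return-outside-function",
                            "return statement outside a function", s)
            elif s.value is not None:
                t = self.types.infer(s.value, scope)
                s.conv_factor = self.types.coerce(t, return_type, s)
            elif return_type.kind != "void":
                self._error("missing-return-value",
                            f"function must return {return_type}", s)
        elif isinstance(s, A.IfStmt):
            for cond, body in s.branches:
                if cond is not None:
                    t = self.types.infer(cond, scope)
                    if t.kind != "boolean":
                        self._error("condition-type",
                                    f"if condition must be boolean, got {t}", cond)
                self._check_statements(body, scope.child("if"), return_type)
        elif isinstance(s, A.WhileStmt):
            t = self.types.infer(s.condition, scope)
            if t.kind != "boolean":
                self._error("condition-type",
                            f"while condition must be boolean, got {t}", s.condition)
            self._check_statements(s.body, scope.child("while"), return_type)
        elif isinstance(s, A.ForStmt):
            start_t = self.types.infer(s.start, scope)
            self.types.infer(s.stop, scope)
            if s.step is not None:
                self.types.infer(s.step, scope)
            body_scope = scope.child("for")
            diag = body_scope.define(Symbol(s.var, LOCAL, start_t))
            if diag:
                self.diagnostics.append(diag)
            self._check_statements(s.body, body_scope, return_type)
        else:
            raise TypeError(f"unknown statement node {type(s).__name__}")

    def _check_assignment(self, s: A.Assignment, scope: SymbolTable) -> None:
        sym = scope.lookup(s.target.name)
        if sym is None:
            self._error("unresolved-name",
                        f"assignment to undeclared name {s.target.name!r}", s.target)
            self.types.infer(s.value, scope)
            return
        s.target.symbol = sym
        if sym.kind in (PARAMETER, INTERNAL):
            self._error("assign-to-constant",
                        f"{sym.kind} {s.target.name!r} is constant during "
                        "simulation and cannot be assigned", s)
        elif sym.kind in (INPUT_PORT, PREDEFINED, KERNEL, EQUATION_VAR):
            self._error("assign-target",
                        f"cannot assign to {sym.kind} {s.target.name!r}", s)
        if s.target.index is not None:
            idx_t = self.types.infer(s.target.index, scope)
            if idx_t.kind != "integer":
                self._error("vector-index-type",
                            f"vector index must be integer, got {idx_t}",
                            s.target.index)
            if sym.vector_size is None:
                self._error("not-a-vector",
                            f"{s.target.name!r} is not a vector but is indexed",
                            s.target)
        value_t = self.types.infer(s.value, scope)
        target_t = sym.type
        if target_t is None:
            return
        s.target.type = target_t
        if s.op in ("=", "+=", "-="):
            s.conv_factor = self.types.coerce(value_t, target_t, s)
        else:  # *= and /= scale by a dimensionless factor
            s.conv_factor = self.types.coerce(value_t, U.REAL, s)

    def _check_call_statement(self, s: A.ExprStmt, scope: SymbolTable) -> None:
        call = s.call
        self.types.infer(call, scope)
        if call.name == "emit_spike" or call.name == "deliver_spike":
            if not self.has_spike_output:
                self._error("no-spike-output",
                            f"{call.name}() requires an 'output: spike' block", s)
        elif call.name == "integrate_odes":
            for arg in call.args:
                if not isinstance(arg, A.VarRef) or arg.index is not None:
                    self._error("integrate-odes-arg",
                                "integrate_odes() arguments must be state-variable "
                                "names", arg)
                    continue
                sym = self.scope.lookup(arg.name)
                if sym is None or sym.kind != STATE or arg.name not in self.equation_vars:
                    self._error("integrate-odes-arg",
                                f"integrate_odes() argument {arg.name!r} must be a "
                                "state variable governed by an equation", arg)


def check_model(model: A.Model) -> list[Diagnostic]:
    """Run all context conditions on a parsed model; returns findings, errors first."""
    return ModelChecker(model).run()


def validate(model: A.Model) -> list[Diagnostic]:
    """Alias for :func:`check_model`."""
    return check_model(model)


__all__ = ["check_model", "validate", "ModelChecker", "has_errors"]
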