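"""Static type inference over expressions.

Every expression is assigned a :class:`~spikelang.units.TypeDesc`.  Addition,
subtraction and comparison require equal dimensions; when only the decadic
prefixes differ, an implicit conversion factor is recorded on the node (and
later folded into evaluation), so ``E_L + 0.5 V`` with ``E_L`` in mV scales
the volt term by 10^3.  Multiplication and division combine dimensions and
scales.  A dimensionful quantity converts to real with a warning; real
converts to integer with a warning (truncation toward zero).  Spike trains
(Dirac deltas) carry dimension time^-1, so convolving them with a kernel
cancels the time dimension of the integral.
"""

from __future__ import annotations

from typing import Optional

from . import ast_nodes as A
from . import units as U
from .diagnostics import Diagnostic
from .symbols import (BUILTIN_FUNCTIONS, FUNCTION, INPUT_PORT, KERNEL,
                      PARAMETER, Symbol, SymbolTable)


class TypeChecker:
    """Annotates expressions with types; accumulates diagnostics."""

    def __init__(self, diagnostics: Optional[list[Diagnostic]] = None):
        self.diagnostics = diagnostics if diagnostics is not None else []
        self._kernel_type_cache: dict[int, U.TypeDesc] = {}

    # -- diagnostics helpers -------------------------------------------------

    def _error(self, code: str, message: str, node) -> None:
        self.diagnostics.append(Diagnostic("error", code, message,
                                           getattr(node, "span", None)))

    def _warn(self, code: str, message: str, node) -> None:
        self.diagnostics.append(Diagnostic("warning", code, message,
                                           getattr(node, "span", None)))

    # -- public entry --------------------------------------------------------

    def infer(self, expr: A.Expression, scope: SymbolTable) -> U.TypeDesc:
        t = self._infer(expr, scope)
        expr.type = t
        return t

    # -- conversion helpers --------------------------------------------------

    def coerce(self, value_type: U.TypeDesc, target: U.TypeDesc, node) -> float:
        """Factor converting a value of ``value_type`` to ``target``.

        Emits diagnostics for lossy or impossible conversions; returns 1.0 on
        error so evaluation can proceed for error recovery.
        """
        if value_type == target:
            return 1.0
        if target.kind == "quantity":
            if value_type.kind == "quantity":
                if value_type.quantity.dimension != target.quantity.dimension:
                    self._error("unit-mismatch",
                                f"cannot convert {value_type} to {target}: "
                                "incompatible dimensions", node)
                    return 1.0
                return U.conversion_factor(value_type.quantity, target.quantity)
            if value_type.kind in ("integer", "real"):
                # a bare number in quantity context: interpreted at the
                # target's own scale (the literal 0 needs no unit)
                return 1.0
        if target.kind == "real":
            return self._to_real_factor(value_type, node)
        if target.kind == "integer":
            if value_type.kind == "real":
                self._warn("real-to-integer",
                           "real value assigned to integer (truncates toward zero)",
                           node)
                return 1.0
            if value_type.kind == "quantity":
                self._warn("quantity-to-integer",
                           "quantity assigned to integer (magnitude truncated)",
                           node)
                return self._to_real_factor(value_type, node, warn=False)
            if value_type.kind == "integer":
                return 1.0
        if target.kind == "boolean" or value_type.kind == "boolean":
            self._error("type-mismatch",
                        f"cannot convert {value_type} to {target}", node)
            return 1.0
        self._error("type-mismatch", f"cannot convert {value_type} to {target}", node)
        return 1.0

    def _to_real_factor(self, t: U.TypeDesc, node, warn: bool = True) -> float:
        if t.kind in ("integer", "real"):
            return 1.0
        if t.kind == "quantity":
            if t.quantity.dimension.is_dimensionless:
                return 10.0 ** t.quantity.scale
            if warn:
                self._warn("quantity-to-real",
                           f"dimensionful {t} used as real (magnitude taken as-is)",
                           node)
            return 1.0
        self._error("type-mismatch", f"cannot use {t} as real", node)
        return 1.0

    @staticmethod
    def _collapse(t: U.TypeDesc) -> U.TypeDesc:
        """Dimensionless quantities at scale 0 are plain reals."""
        if (t.kind == "quantity" and t.quantity.dimension.is_dimensionless
                and t.quantity.scale == 0):
            return U.REAL
        return t

    # -- inference -----------------------------------------------------------

    def _infer(self, expr: A.Expression, scope: SymbolTable) -> U.TypeDesc:
        if isinstance(expr, A.NumberLiteral):
            if expr.unit is not None:
                try:
                    return U.quantity(U.parse_unit(expr.unit))
                except U.UnitError as exc:
                    self._error("unknown-unit", str(exc), expr)
                    return U.REAL
            return U.INTEGER if expr.is_int else U.REAL
        if isinstance(expr, A.BooleanLiteral):
            return U.BOOLEAN
        if isinstance(expr, A.StringLiteral):
            return U.STRING
        if isinstance(expr, A.VarRef):
            return self._infer_varref(expr, scope)
        if isinstance(expr, A.UnaryOp):
            return self._infer_unary(expr, scope)
        if isinstance(expr, A.BinaryOp):
            return self._infer_binary(expr, scope)
        if isinstance(expr, A.FunctionCall):
            return self._infer_call(expr, scope)
        if isinstance(expr, A.Convolve):
            return self._infer_convolve(expr, scope)
        raise TypeError(f"cannot infer type of {type(expr).__name__}")

    def _infer_varref(self, expr: A.VarRef, scope: SymbolTable) -> U.TypeDesc:
        sym = scope.lookup(expr.name)
        if sym is None:
            q = U.resolve_unit_name(expr.name) if "'" not in expr.name else None
            if q is None and "'" not in expr.name:
                try:
                    q = U.parse_unit(expr.name)
                except U.UnitError:
                    q = None
            if q is not None:
                expr.is_unit_literal = True
                return U.quantity(q)
            self._error("unresolved-name", f"name {expr.name!r} is not defined", expr)
            return U.REAL
        expr.symbol = sym
        if sym.kind == KERNEL:
            self._error("kernel-outside-convolve",
                        f"kernel {expr.name!r} may only appear inside convolve()",
                        expr)
            return U.REAL
        if sym.kind == FUNCTION:
            self._error("function-as-value",
                        f"function {expr.name!r} referenced without a call", expr)
            return U.REAL
        if expr.index is not None:
            if sym.vector_size is None:
                self._error("not-a-vector",
                            f"{expr.name!r} is not a vector but is indexed", expr)
            idx_t = self.infer(expr.index, scope)
            if idx_t.kind != "integer":
                self._error("vector-index-type",
                            f"vector index must be integer, got {idx_t}", expr.index)
        if sym.kind == INPUT_PORT and sym.port_kind == "spike":
            # outside convolve, a spike-port name yields the event weight
            return U.REAL
        return sym.type if sym.type is not None else U.REAL

    def _infer_unary(self, expr: A.UnaryOp, scope: SymbolTable) -> U.TypeDesc:
        t = self.infer(expr.operand, scope)
        if expr.op == "not":
            if t.kind != "boolean":
                self._error("boolean-expected", f"'not' needs a boolean, got {t}", expr)
            return U.BOOLEAN
        if not t.is_numeric:
            self._error("numeric-expected", f"unary {expr.op!r} needs a number, got {t}",
                        expr)
            return U.REAL
        return t

    def _unify_additive(self, node, lt: U.TypeDesc, rt: U.TypeDesc,
                        what: str) -> U.TypeDesc:
        """Common type of two operands that must share a dimension."""
        if not lt.is_numeric or not rt.is_numeric:
            self._error("numeric-expected",
                        f"{what} needs numeric operands, got {lt} and {rt}", node)
            return U.REAL
        if lt.kind == "quantity" and rt.kind == "quantity":
            if lt.quantity.dimension != rt.quantity.dimension:
                self._error("unit-mismatch",
                            f"incompatible units in {what}: {lt} vs {rt}", node)
                return lt
            if isinstance(node, A.BinaryOp):
                node.factor_right = U.conversion_factor(rt.quantity, lt.quantity)
            elif isinstance(node, A.FunctionCall):
                node.arg_factors[1] = U.conversion_factor(rt.quantity, lt.quantity)
            return lt
        if lt.kind == "quantity" or rt.kind == "quantity":
            qt, other = (lt, rt) if lt.kind == "quantity" else (rt, lt)
            factor = self._to_real_factor(qt, node)
            if isinstance(node, A.BinaryOp):
                if lt.kind == "quantity":
                    node.factor_left = factor
                else:
                    node.factor_right = factor
            elif isinstance(node, A.FunctionCall):
                node.arg_factors[0 if lt.kind == "quantity" else 1] = factor
            return U.REAL
        if lt.kind == "integer" and rt.kind == "integer":
            return U.INTEGER
        return U.REAL

    def _infer_binary(self, expr: A.BinaryOp, scope: SymbolTable) -> U.TypeDesc:
        lt = self.infer(expr.left, scope)
        rt = self.infer(expr.right, scope)
        op = expr.op
        if op in ("and", "or"):
            for t, side in ((lt, expr.left), (rt, expr.right)):
                if t.kind != "boolean":
                    self._error("boolean-expected",
                                f"{op!r} needs boolean operands, got {t}", side)
            return U.BOOLEAN
        if op in ("==", "!=", "<", "<=", ">", ">="):
            self._unify_additive(expr, lt, rt, "comparison")
            return U.BOOLEAN
        if op in ("+", "-"):
            return self._unify_additive(expr, lt, rt, f"{op!r}")
        if op in ("*", "/"):
            if not lt.is_numeric or not rt.is_numeric:
                self._error("numeric-expected",
                            f"{op!r} needs numeric operands, got {lt} and {rt}", expr)
                return U.REAL
            lq = lt.quantity if lt.kind == "quantity" else U.QuantityType(U.DIMENSIONLESS, 0)
            rq = rt.quantity if rt.kind == "quantity" else U.QuantityType(U.DIMENSIONLESS, 0)
            q = lq * rq if op == "*" else lq / rq
            if lt.kind != "quantity" and rt.kind != "quantity":
                if op == "*" and lt.kind == "integer" and rt.kind == "integer":
                    return U.INTEGER
                return U.REAL
            return self._collapse(U.quantity(q))
        if op == "**":
            if lt.kind == "quantity":
                k = _integer_exponent(expr.right)
                if k is None:
                    self._error("unit-power",
                                "a quantity can only be raised to an integer "
                                "literal power", expr)
                    return lt
                return self._collapse(U.quantity(lt.quantity ** k))
            if not lt.is_numeric or not rt.is_numeric:
                self._error("numeric-expected",
                            f"'**' needs numeric operands, got {lt} and {rt}", expr)
                return U.REAL
            if lt.kind == "integer" and rt.kind == "integer":
                return U.INTEGER
            return U.REAL
        raise ValueError(f"unknown operator {op!r}")

    def _infer_call(self, expr: A.FunctionCall, scope: SymbolTable) -> U.TypeDesc:
        expr.arg_factors = [1.0] * len(expr.args)
        name = expr.name
        arg_types = [self.infer(a, scope) for a in expr.args]

        if name.startswith("__post__"):
            # accessor into the postsynaptic neuron, injected by co-generation;
            # returns the moved variable's value at the query time
            return U.REAL
        if name in BUILTIN_FUNCTIONS:
            info = BUILTIN_FUNCTIONS[name]
            arity = info["arity"]
            if arity >= 0 and len(expr.args) != arity:
                self._error("arity",
                            f"{name}() takes {arity} argument(s), got {len(expr.args)}",
                            expr)
                return info["returns"] or U.REAL
            if name == "integrate_odes":
                return U.VOID
            if name in ("emit_spike",):
                return U.VOID
            if name == "deliver_spike":
                return U.VOID
            if name == "abs":
                return arg_types[0]
            if name in ("min", "max"):
                return self._unify_additive(expr, arg_types[0], arg_types[1], name)
            # scalar math on reals: dimensionless quantities convert silently,
            # dimensionful ones with a warning
            for i, t in enumerate(arg_types):
                if t.kind == "boolean" or t.kind == "string":
                    self._error("numeric-expected",
                                f"{name}() argument must be numeric, got {t}",
                                expr.args[i])
                else:
                    expr.arg_factors[i] = self._to_real_factor(t, expr.args[i])
            return info["returns"]

        sym = scope.lookup(name)
        if sym is None or sym.kind != FUNCTION:
            self._error("unresolved-function", f"function {name!r} is not defined", expr)
            return U.REAL
        expr.symbol = sym if isinstance(expr, A.VarRef) else None
        if sym.signature is not None:
            params, ret = sym.signature
            if len(params) != len(arg_types):
                self._error("arity",
                            f"{name}() takes {len(params)} argument(s), "
                            f"got {len(arg_types)}", expr)
            else:
                for i, (pt, at) in enumerate(zip(params, arg_types)):
                    expr.arg_factors[i] = self.coerce(at, pt, expr.args[i])
            return ret
        return sym.type if sym.type is not None else U.REAL

    def _infer_convolve(self, expr: A.Convolve, scope: SymbolTable) -> U.TypeDesc:
        ksym = scope.lookup(expr.kernel)
        psym = scope.lookup(expr.port)
        ok = True
        if ksym is None or ksym.kind != KERNEL:
            self._error("convolve-kernel",
                        f"convolve() first argument {expr.kernel!r} must name a kernel",
                        expr)
            ok = False
        if psym is None or psym.kind != INPUT_PORT or psym.port_kind != "spike":
            self._error("convolve-port",
                        f"convolve() second argument {expr.port!r} must name a "
                        "spike input port", expr)
            ok = False
        if not ok:
            return U.REAL
        # the spike train carries time^-1; the convolution integral
        # contributes time, so the result has the kernel's own dimension
        key = id(ksym.node)
        if key not in self._kernel_type_cache:
            kscope = scope.child(f"kernel {expr.kernel}")
            kt = self.infer(ksym.node.expression, kscope)
            self._kernel_type_cache[key] = self._collapse(kt)
        return self._kernel_type_cache[key]


def _integer_exponent(expr: A.Expression) -> Optional[int]:
    if isinstance(expr, A.NumberLiteral) and expr.is_int and expr.unit is None:
        return int(expr.value)
    if isinstance(expr, A.UnaryOp) and expr.op in ("-", "+"):
        k = _integer_exponent(expr.operand)
        if k is not None:
            return -k if expr.op == "-" else k
    return None


def infer_type(expr: A.Expression, scope: SymbolTable) -> tuple[U.TypeDesc, list[Diagnostic]]:
    """Infer the type of one expression against a scope (convenience wrapper)."""
    checker = TypeChecker()
    t = checker.infer(expr, scope)
    return t, checker.diagnostics
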