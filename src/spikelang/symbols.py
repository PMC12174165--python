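"""Scoped symbol tables and the predefined (builtin) scope.

Each block gets its own scope with a parent link; lookups resolve through
parents.  The root scope holds the predefined variables ``t`` (global
simulation time, in ms) and ``e`` (Euler's constant) plus the builtin
functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from . import ast_nodes as A
from . import units as U
from .diagnostics import Diagnostic

# symbol kinds
STATE = "state"
PARAMETER = "parameter"
INTERNAL = "internal"
INPUT_PORT = "input-port"
FUNCTION = "function"
LOCAL = "local"
EQUATION_VAR = "equation-variable"  # derivative symbols such as V_m'
KERNEL = "kernel"
INLINE = "inline"
PREDEFINED = "predefined"


@dataclass
class Symbol:
    name: str
    kind: str
    type: Optional[U.TypeDesc] = None
    node: object = None
    vector_size: object = None  # int, or name of the sizing parameter
    port_kind: Optional[str] = None  # for input ports: spike | continuous
    # for functions: ([param TypeDesc], return TypeDesc)
    signature: Optional[tuple[list[U.TypeDesc], U.TypeDesc]] = None


@dataclass
class SymbolTable:
    name: str = "<scope>"
    parent: Optional["SymbolTable"] = None
    entries: dict[str, Symbol] = field(default_factory=dict)
    children: list["SymbolTable"] = field(default_factory=list)

    def child(self, name: str) -> "SymbolTable":
        scope = SymbolTable(name=name, parent=self)
        self.children.append(scope)
        return scope

    def define(self, sym: Symbol) -> Optional[Diagnostic]:
        """Insert a symbol; returns a duplicate-name diagnostic on collision."""
        if sym.name in self.entries:
            span = getattr(sym.node, "span", None)
            return Diagnostic("error", "duplicate-name",
                              f"name {sym.name!r} is already defined in this scope",
                              span)
        self.entries[sym.name] = sym
        return None

    def lookup(self, name: str) -> Optional[Symbol]:
        scope: Optional[SymbolTable] = self
        while scope is not None:
            if name in scope.entries:
                return scope.entries[name]
            scope = scope.parent
        return None


# -- builtin functions ------------------------------------------------------
# (param kinds, return kind); "real" parameters also accept integers and
# dimensionless quantities.  None return type means "same as first argument".

BUILTIN_FUNCTIONS: dict[str, dict] = {
    "exp": {"arity": 1, "returns": U.REAL},
    "ln": {"arity": 1, "returns": U.REAL},
    "log10": {"arity": 1, "returns": U.REAL},
    "sqrt": {"arity": 1, "returns": U.REAL},
    "sin": {"arity": 1, "returns": U.REAL},
    "cos": {"arity": 1, "returns": U.REAL},
    "tan": {"arity": 1, "returns": U.REAL},
    "erf": {"arity": 1, "returns": U.REAL},
    "ceil": {"arity": 1, "returns": U.REAL},
    "floor": {"arity": 1, "returns": U.REAL},
    "abs": {"arity": 1, "returns": None},      # same type as its argument
    "min": {"arity": 2, "returns": None},      # common type of both arguments
    "max": {"arity": 2, "returns": None},
    "random_normal": {"arity": 2, "returns": U.REAL},
    "random_uniform": {"arity": 2, "returns": U.REAL},
    "random_poisson": {"arity": 1, "returns": U.INTEGER},
    "integrate_odes": {"arity": -1, "returns": U.VOID},  # variadic state names
    "emit_spike": {"arity": 0, "returns": U.VOID},
    "deliver_spike": {"arity": 1, "returns": U.VOID},  # synapse: forward weight
}

EULER_E = math.e


def make_root_scope() -> SymbolTable:
    root = SymbolTable(name="<predefined>")
    root.define(Symbol("t", PREDEFINED, U.quantity(U.MS)))
    root.define(Symbol("e", PREDEFINED, U.REAL))
    for fname in BUILTIN_FUNCTIONS:
        root.define(Symbol(fname, FUNCTION))
    return root


def build_symbol_tables(model: A.Model) -> tuple[SymbolTable, list[Diagnostic]]:
    """Construct the scope hierarchy for a parsed model.

    Returns the model scope (whose parent is the predefined root scope) and
    any duplicate-name diagnostics.  Declared types are resolved here;
    malformed type annotations yield diagnostics and the symbol is entered
    untyped so downstream lookups still succeed.
    """
    diags: list[Diagnostic] = []
    root = make_root_scope()
    scope = root.child(f"model {model.name}")

    def resolve_type(text: str, span) -> Optional[U.TypeDesc]:
        try:
            return U.parse_type(text)
        except U.UnitError as exc:
            diags.append(Diagnostic("error", "unknown-type", str(exc), span))
            return None

    kind_by_block = {"state": STATE, "parameters": PARAMETER, "internals": INTERNAL}
    for block in model.blocks:
        if isinstance(block, A.DeclarationsBlock):
            for d in block.declarations:
                d.resolved_type = resolve_type(d.declared_type, d.span)
                diag = scope.define(Symbol(d.name, kind_by_block[block.kind],
                                           d.resolved_type, d, vector_size=d.size))
                if diag:
                    diags.append(diag)
        elif isinstance(block, A.InputBlock):
            for p in block.ports:
                if p.declared_unit is not None:
                    p.resolved_type = resolve_type(p.declared_unit, p.span)
                else:
                    p.resolved_type = U.REAL
                diag = scope.define(Symbol(p.name, INPUT_PORT, p.resolved_type,
                                           p, port_kind=p.kind))
                if diag:
                    diags.append(diag)
        elif isinstance(block, A.EquationsBlock):
            for item in block.items:
                if isinstance(item, A.KernelDef):
                    diag = scope.define(Symbol(item.name, KERNEL, U.REAL, item))
                    if diag:
                        diags.append(diag)
                elif isinstance(item, A.InlineDef):
                    item.resolved_type = resolve_type(item.declared_type, item.span)
                    diag = scope.define(Symbol(item.name, INLINE,
                                               item.resolved_type, item))
                    if diag:
                        diags.append(diag)
        elif isinstance(block, A.FunctionDef):
            params = [resolve_type(t, block.span) for _, t in block.params]
            ret = (resolve_type(block.return_type, block.span)
                   if block.return_type else U.VOID)
            sig = (params, ret) if all(p is not None for p in params) and ret is not None else None
            diag = scope.define(Symbol(block.name, FUNCTION, ret, block, signature=sig))
            if diag:
                diags.append(diag)

    # derivative symbols: an order-n equation on x introduces x', x'', ...
    eq_block = model.equations
    if eq_block is not None:
        for item in eq_block.items:
            if not isinstance(item, A.Equation):
                continue
            base = scope.lookup(item.lhs_variable)
            base_q = (base.type.quantity if base is not None and base.type is not None
                      and base.type.kind == "quantity" else U.QuantityType(U.DIMENSIONLESS, 0))
            for k in range(1, item.order + 1):
                name = item.lhs_variable + "'" * k
                if scope.lookup(name) is None:
                    deriv_q = base_q / (U.MS ** k)
                    scope.define(Symbol(name, EQUATION_VAR, U.quantity(deriv_q), item))

    return scope, diags
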