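"""Abstract syntax tree for the modeling language.

Node classes are plain dataclasses.  Structural equality (``==``) deliberately
ignores source spans and analysis annotations (resolved types, implicit
conversion factors), so that a parse -> print -> parse round trip compares
equal.  ``walk`` yields nodes in a deterministic pre-order for generic passes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

from .units import TypeDesc

Span = tuple[int, int]  # (line, column), 1-based


def _meta(default=None):
    """An annotation slot: carried on the node but excluded from equality."""
    return field(default=default, compare=False, repr=False)


@dataclass
class Node:
    pass


# -- expressions ------------------------------------------------------------

@dataclass
class Expression(Node):
    pass


@dataclass
class NumberLiteral(Expression):
    value: float
    is_int: bool = False
    unit: Optional[str] = None  # textual unit suffix, e.g. "10 ms"
    span: Optional[Span] = _meta()
    type: Optional[TypeDesc] = _meta()


@dataclass
class BooleanLiteral(Expression):
    value: bool
    span: Optional[Span] = _meta()
    type: Optional[TypeDesc] = _meta()


@dataclass
class StringLiteral(Expression):
    value: str
    span: Optional[Span] = _meta()
    type: Optional[TypeDesc] = _meta()


@dataclass
class VarRef(Expression):
    name: str
    index: Optional[Expression] = None  # vector element access
    span: Optional[Span] = _meta()
    type: Optional[TypeDesc] = _meta()
    # filled by name resolution; "unit-literal" references (a bare unit name
    # in value position, standing for 1 of that unit) get is_unit_literal
    symbol: object = _meta()
    is_unit_literal: bool = _meta(False)


@dataclass
class UnaryOp(Expression):
    op: str  # '-', '+', 'not'
    operand: Expression = None
    span: Optional[Span] = _meta()
    type: Optional[TypeDesc] = _meta()


@dataclass
class BinaryOp(Expression):
    op: str  # arithmetic: + - * / ** ; comparison: == != < <= > >= ; logic: and or
    left: Expression = None
    right: Expression = None
    span: Optional[Span] = _meta()
    type: Optional[TypeDesc] = _meta()
    # implicit decadic conversion factors applied to each operand when
    # prefixes differ (1.0 when none); recorded by the type checker
    factor_left: float = _meta(1.0)
    factor_right: float = _meta(1.0)


@dataclass
class FunctionCall(Expression):
    name: str
    args: list[Expression] = field(default_factory=list)
    span: Optional[Span] = _meta()
    type: Optional[TypeDesc] = _meta()
    # per-argument implicit conversion factors recorded by the type checker
    arg_factors: Optional[list[float]] = _meta()


@dataclass
class Convolve(Expression):
    """``convolve(kernel, port)``: spike train filtered by a response kernel."""

    kernel: str
    port: str
    span: Optional[Span] = _meta()
    type: Optional[TypeDesc] = _meta()


# -- statements -------------------------------------------------------------

@dataclass
class Statement(Node):
    pass


@dataclass
class Declaration(Node):
    """A variable declaration: ``name type [size] = initializer  # doc``."""

    name: str
    declared_type: str
    size: Optional[Union[int, str]] = None  # literal or name of a parameter
    initializer: Optional[Expression] = None
    doc_comment: Optional[str] = None
    span: Optional[Span] = _meta()
    resolved_type: Optional[TypeDesc] = _meta()
    init_factor: float = _meta(1.0)  # implicit factor initializer -> declared unit


@dataclass
class DeclarationStmt(Statement):
    declaration: Declaration = None
    span: Optional[Span] = _meta()


@dataclass
class Assignment(Statement):
    target: VarRef = None
    op: str = "="  # = += -= *= /=
    value: Expression = None
    span: Optional[Span] = _meta()
    conv_factor: float = _meta(1.0)  # implicit factor value -> target unit


@dataclass
class IfStmt(Statement):
    # (condition, body) per if/elif arm; else arm has condition None
    branches: list[tuple[Optional[Expression], list[Statement]]] = field(default_factory=list)
    span: Optional[Span] = _meta()


@dataclass
class WhileStmt(Statement):
    condition: Expression = None
    body: list[Statement] = field(default_factory=list)
    span: Optional[Span] = _meta()


@dataclass
class ForStmt(Statement):
    var: str = ""
    start: Expression = None
    stop: Expression = None
    step: Optional[Expression] = None
    body: list[Statement] = field(default_factory=list)
    span: Optional[Span] = _meta()


@dataclass
class ExprStmt(Statement):
    """A bare call statement: integrate_odes(), emit_spike(), user functions."""

    call: FunctionCall = None
    span: Optional[Span] = _meta()


@dataclass
class ReturnStmt(Statement):
    value: Optional[Expression] = None
    span: Optional[Span] = _meta()
    conv_factor: float = _meta(1.0)


# -- equations-block items --------------------------------------------------

@dataclass
class Equation(Node):
    """``x'' = rhs``: a differential equation of order >= 1 on a state variable."""

    lhs_variable: str
    order: int
    rhs: Expression = None
    span: Optional[Span] = _meta()
    # factor converting the rhs magnitude to (state unit)/ms**order
    rhs_factor: float = _meta(1.0)


@dataclass
class KernelDef(Node):
    """A response kernel, an expression in the time variable t."""

    name: str
    expression: Expression = None
    span: Optional[Span] = _meta()


@dataclass
class InlineDef(Node):
    """A named expression substituted verbatim where referenced."""

    name: str
    declared_type: str = "real"
    expression: Expression = None
    span: Optional[Span] = _meta()
    resolved_type: Optional[TypeDesc] = _meta()
    conv_factor: float = _meta(1.0)  # implicit factor expression -> declared unit


# -- blocks -----------------------------------------------------------------

@dataclass
class Block(Node):
    pass


@dataclass
class DeclarationsBlock(Block):
    kind: str = "state"  # state | parameters | internals
    declarations: list[Declaration] = field(default_factory=list)
    span: Optional[Span] = _meta()


@dataclass
class EquationsBlock(Block):
    items: list[Union[Equation, KernelDef, InlineDef]] = field(default_factory=list)
    span: Optional[Span] = _meta()


@dataclass
class InputPort(Node):
    name: str
    kind: str = "spike"  # spike | continuous
    declared_unit: Optional[str] = None
    span: Optional[Span] = _meta()
    resolved_type: Optional[TypeDesc] = _meta()


@dataclass
class InputBlock(Block):
    ports: list[InputPort] = field(default_factory=list)
    span: Optional[Span] = _meta()


@dataclass
class OutputBlock(Block):
    kind: str = "spike"  # spike | continuous
    span: Optional[Span] = _meta()


@dataclass
class UpdateBlock(Block):
    statements: list[Statement] = field(default_factory=list)
    span: Optional[Span] = _meta()


@dataclass
class OnReceive(Block):
    port: str = ""
    priority: Optional[int] = None
    statements: list[Statement] = field(default_factory=list)
    span: Optional[Span] = _meta()


@dataclass
class OnCondition(Block):
    condition: Expression = None
    statements: list[Statement] = field(default_factory=list)
    span: Optional[Span] = _meta()


@dataclass
class FunctionDef(Block):
    name: str = ""
    params: list[tuple[str, str]] = field(default_factory=list)  # (name, type text)
    return_type: Optional[str] = None
    statements: list[Statement] = field(default_factory=list)
    span: Optional[Span] = _meta()


_SINGLETON_KINDS = ("state", "parameters", "internals", "equations",
                    "input", "output", "update")


@dataclass
class Model(Node):
    name: str
    docstring: Optional[str] = None
    blocks: list[Block] = field(default_factory=list)
    span: Optional[Span] = _meta()

    # convenience accessors -------------------------------------------------
    def _decl_block(self, kind: str) -> Optional[DeclarationsBlock]:
        for b in self.blocks:
            if isinstance(b, DeclarationsBlock) and b.kind == kind:
                return b
        return None

    @property
    def state(self) -> Optional[DeclarationsBlock]:
        return self._decl_block("state")

    @property
    def parameters(self) -> Optional[DeclarationsBlock]:
        return self._decl_block("parameters")

    @property
    def internals(self) -> Optional[DeclarationsBlock]:
        return self._decl_block("internals")

    @property
    def equations(self) -> Optional[EquationsBlock]:
        for b in self.blocks:
            if isinstance(b, EquationsBlock):
                return b
        return None

    @property
    def input(self) -> Optional[InputBlock]:
        for b in self.blocks:
            if isinstance(b, InputBlock):
                return b
        return None

    @property
    def output(self) -> Optional[OutputBlock]:
        for b in self.blocks:
            if isinstance(b, OutputBlock):
                return b
        return None

    @property
    def update(self) -> Optional[UpdateBlock]:
        for b in self.blocks:
            if isinstance(b, UpdateBlock):
                return b
        return None

    @property
    def on_receive(self) -> list[OnReceive]:
        return [b for b in self.blocks if isinstance(b, OnReceive)]

    @property
    def on_condition(self) -> list[OnCondition]:
        return [b for b in self.blocks if isinstance(b, OnCondition)]

    @property
    def functions(self) -> list[FunctionDef]:
        return [b for b in self.blocks if isinstance(b, FunctionDef)]

    def spike_ports(self) -> list[InputPort]:
        blk = self.input
        return [p for p in blk.ports if p.kind == "spike"] if blk else []

    def continuous_ports(self) -> list[InputPort]:
        blk = self.input
        return [p for p in blk.ports if p.kind == "continuous"] if blk else []


# -- generic traversal ------------------------------------------------------

def children(node: Node) -> Iterator[Node]:
    """Yield direct child nodes in field-declaration order."""
    for f in dataclasses.fields(node):
        if not f.compare:
            continue
        value = getattr(node, f.name)
        if isinstance(value, Node):
            yield value
        elif isinstance(value, list):
            for item in value:
                if isinstance(item, Node):
                    yield item
                elif isinstance(item, tuple):
                    for sub in item:
                        if isinstance(sub, Node):
                            yield sub
                        elif isinstance(sub, list):
                            yield from (s for s in sub if isinstance(s, Node))


def walk(node: Node) -> Iterator[Node]:
    """Pre-order traversal over the subtree rooted at ``node``."""
    yield node
    for child in children(node):
        yield from walk(child)
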