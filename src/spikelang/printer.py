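"""Render an AST back to model source text.

The printer is the inverse of the parser up to layout: for any well-formed
AST, ``parse_model(print_model(ast))`` is structurally equal to ``ast``.
Transformed models (lowered, co-generated) can therefore always be inspected
and re-ingested as ordinary source text.
"""

from __future__ import annotations

from . import ast_nodes as A

_INDENT = "    "

# operator precedence, higher binds tighter
_PREC = {
    "or": 1, "and": 2,
    "==": 4, "!=": 4, "<": 4, "<=": 4, ">": 4, ">=": 4,
    "+": 5, "-": 5, "*": 6, "/": 6, "**": 8,
}
_RIGHT_ASSOC = {"**"}


def print_expression(expr: A.Expression) -> str:
    return _expr(expr, 0)


def _expr(e: A.Expression, parent_prec: int) -> str:
    if isinstance(e, A.NumberLiteral):
        text = str(int(e.value)) if e.is_int else repr(e.value)
        if e.unit:
            text += f" {e.unit}"
        return text
    if isinstance(e, A.BooleanLiteral):
        return "true" if e.value else "false"
    if isinstance(e, A.StringLiteral):
        return f'"{e.value}"'
    if isinstance(e, A.VarRef):
        if e.index is not None:
            return f"{e.name}[{_expr(e.index, 0)}]"
        return e.name
    if isinstance(e, A.UnaryOp):
        prec = 3 if e.op == "not" else 7
        sep = " " if e.op == "not" else ""
        text = f"{e.op}{sep}{_expr(e.operand, prec)}"
        return f"({text})" if prec < parent_prec else text
    if isinstance(e, A.BinaryOp):
        prec = _PREC[e.op]
        if e.op in _RIGHT_ASSOC:
            left = _expr(e.left, prec + 1)
            right = _expr(e.right, prec)
        else:
            left = _expr(e.left, prec)
            right = _expr(e.right, prec + 1)
        text = f"{left} {e.op} {right}"
        return f"({text})" if prec < parent_prec else text
    if isinstance(e, A.FunctionCall):
        args = ", ".join(_expr(a, 0) for a in e.args)
        return f"{e.name}({args})"
    if isinstance(e, A.Convolve):
        return f"convolve({e.kernel}, {e.port})"
    raise TypeError(f"cannot print expression node {type(e).__name__}")


def _declaration(d: A.Declaration) -> str:
    text = f"{d.name} {d.declared_type}"
    if d.size is not None:
        text += f"[{d.size}]"
    if d.initializer is not None:
        text += f" = {_expr(d.initializer, 0)}"
    if d.doc_comment:
        text += f" # {d.doc_comment}"
    return text


def _statements(stmts: list[A.Statement], level: int, out: list[str]) -> None:
    pad = _INDENT * level
    for s in stmts:
        if isinstance(s, A.Assignment):
            target = s.target.name
            if s.target.index is not None:
                target += f"[{_expr(s.target.index, 0)}]"
            out.append(f"{pad}{target} {s.op} {_expr(s.value, 0)}")
        elif isinstance(s, A.DeclarationStmt):
            out.append(pad + _declaration(s.declaration))
        elif isinstance(s, A.ExprStmt):
            out.append(pad + _expr(s.call, 0))
        elif isinstance(s, A.ReturnStmt):
            out.append(f"{pad}return {_expr(s.value, 0)}" if s.value is not None
                       else f"{pad}return")
        elif isinstance(s, A.IfStmt):
            for i, (cond, body) in enumerate(s.branches):
                if cond is None:
                    out.append(f"{pad}else:")
                elif i == 0:
                    out.append(f"{pad}if {_expr(cond, 0)}:")
                else:
                    out.append(f"{pad}elif {_expr(cond, 0)}:")
                _statements(body, level + 1, out)
        elif isinstance(s, A.WhileStmt):
            out.append(f"{pad}while {_expr(s.condition, 0)}:")
            _statements(s.body, level + 1, out)
        elif isinstance(s, A.ForStmt):
            head = f"{pad}for {s.var} in {_expr(s.start, 0)} ... {_expr(s.stop, 0)}"
            if s.step is not None:
                head += f" step {_expr(s.step, 0)}"
            out.append(head + ":")
            _statements(s.body, level + 1, out)
        else:
            raise TypeError(f"cannot print statement node {type(s).__name__}")


def print_model(model: A.Model) -> str:
    """Render the model as parseable source text."""
    out: list[str] = [f"model {model.name}:"]
    if model.docstring is not None:
        out.append(f'{_INDENT}"""{model.docstring}"""')
    for block in model.blocks:
        if isinstance(block, A.DeclarationsBlock):
            out.append(f"{_INDENT}{block.kind}:")
            for d in block.declarations:
                out.append(_INDENT * 2 + _declaration(d))
        elif isinstance(block, A.EquationsBlock):
            out.append(f"{_INDENT}equations:")
            for item in block.items:
                if isinstance(item, A.KernelDef):
                    out.append(f"{_INDENT * 2}kernel {item.name} = "
                               f"{_expr(item.expression, 0)}")
                elif isinstance(item, A.InlineDef):
                    out.append(f"{_INDENT * 2}inline {item.name} "
                               f"{item.declared_type} = {_expr(item.expression, 0)}")
                else:
                    primes = "'" * item.order
                    out.append(f"{_INDENT * 2}{item.lhs_variable}{primes} = "
                               f"{_expr(item.rhs, 0)}")
        elif isinstance(block, A.InputBlock):
            out.append(f"{_INDENT}input:")
            for p in block.ports:
                unit = f" {p.declared_unit}" if p.declared_unit else ""
                out.append(f"{_INDENT * 2}{p.name}{unit} <- {p.kind}")
        elif isinstance(block, A.OutputBlock):
            out.append(f"{_INDENT}output:")
            out.append(f"{_INDENT * 2}{block.kind}")
        elif isinstance(block, A.UpdateBlock):
            out.append(f"{_INDENT}update:")
            _statements(block.statements, 2, out)
        elif isinstance(block, A.OnReceive):
            prio = f", priority={block.priority}" if block.priority is not None else ""
            out.append(f"{_INDENT}onReceive({block.port}{prio}):")
            _statements(block.statements, 2, out)
        elif isinstance(block, A.OnCondition):
            out.append(f"{_INDENT}onCondition({_expr(block.condition, 0)}):")
            _statements(block.statements, 2, out)
        elif isinstance(block, A.FunctionDef):
            params = ", ".join(f"{n} {t}" for n, t in block.params)
            ret = f" {block.return_type}" if block.return_type else ""
            out.append(f"{_INDENT}function {block.name}({params}){ret}:")
            _statements(block.statements, 2, out)
        else:
            raise TypeError(f"cannot print block node {type(block).__name__}")
    return "\n".join(out) + "\n"
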