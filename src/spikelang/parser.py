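"""Recursive-descent parser: token stream -> :class:`~spikelang.ast_nodes.Model`.

The surface syntax is block-structured and indentation-based:

.. code-block:: text

    model iaf:
        \"\"\"Leaky integrate-and-fire.\"\"\"
        state:
            V_m mV = E_L    # membrane potential
        parameters:
            E_L mV = -70 mV
            tau_m ms = 10 ms
        equations:
            V_m' = -(V_m - E_L) / tau_m
        input:
            spikes_in <- spike
        output:
            spike
        update:
            integrate_odes()
        onCondition(V_m >= -55 mV):
            emit_spike()
            V_m = E_L

Every singleton block (state/parameters/internals/equations/input/output/
update) may appear at most once; onReceive/onCondition/function blocks may
repeat.  Unit names in type position and unit suffixes on numeric literals are
kept as plain text here; resolution happens in the type checker.
"""

from __future__ import annotations

from typing import Optional

from . import ast_nodes as A
from .diagnostics import error
from .lexer import (COMMENT, DEDENT, EOF, INDENT, NAME, NEWLINE, NUMBER, OP,
                    STRING, KEYWORDS, Token, tokenize)

_ASSIGN_OPS = ("=", "+=", "-=", "*=", "/=")
_CMP_OPS = ("==", "!=", "<", "<=", ">", ">=")


class Parser:
    def __init__(self, tokens: list[Token], origin: str = "<memory>"):
        self.tokens = tokens
        self.pos = 0
        self.origin = origin

    # -- token-stream helpers ----------------------------------------------

    def _peek(self, skip_comments: bool = True) -> Token:
        pos = self.pos
        while skip_comments and self.tokens[pos].type == COMMENT:
            pos += 1
        return self.tokens[pos]

    def _advance(self, skip_comments: bool = True) -> Token:
        while skip_comments and self.tokens[self.pos].type == COMMENT:
            self.pos += 1
        tok = self.tokens[self.pos]
        if tok.type != EOF:
            self.pos += 1
        return tok

    def _at(self, type_: str, value: Optional[str] = None) -> bool:
        tok = self._peek()
        return tok.type == type_ and (value is None or tok.value == value)

    def _expect(self, type_: str, value: Optional[str] = None) -> Token:
        tok = self._advance()
        if tok.type != type_ or (value is not None and tok.value != value):
            want = value if value is not None else type_
            raise error("syntax", f"expected {want!r}, found {tok}",
                        (tok.line, tok.col), self.origin)
        return tok

    def _fail(self, msg: str) -> Exception:
        tok = self._peek()
        return error("syntax", f"{msg} (found {tok})", (tok.line, tok.col), self.origin)

    def _skip_newlines(self) -> None:
        while self._at(NEWLINE):
            self._advance()

    def _trailing_comment(self) -> Optional[str]:
        """Consume a comment token sitting before the line's NEWLINE, if any."""
        if self.tokens[self.pos].type == COMMENT:
            tok = self.tokens[self.pos]
            self.pos += 1
            return tok.value
        return None

    # -- model structure -----------------------------------------------------

    def parse_model(self) -> A.Model:
        self._skip_newlines()
        head = self._expect(NAME, "model")
        name = self._expect(NAME).value
        self._expect(OP, ":")
        self._expect(NEWLINE)
        self._expect(INDENT)
        self._skip_newlines()

        docstring = None
        if self._at(STRING):
            docstring = self._advance().value
            if self._at(NEWLINE):
                self._advance()
            self._skip_newlines()

        blocks: list[A.Block] = []
        seen_singletons: set[str] = set()
        while not self._at(DEDENT) and not self._at(EOF):
            block = self._parse_block()
            kind = self._singleton_kind(block)
            if kind is not None:
                if kind in seen_singletons:
                    raise error("duplicate-block",
                                f"duplicate {kind!r} block in model {name!r}",
                                block.span, self.origin)
                seen_singletons.add(kind)
            blocks.append(block)
            self._skip_newlines()
        if self._at(DEDENT):
            self._advance()
        self._skip_newlines()
        self._expect(EOF)
        return A.Model(name=name, docstring=docstring, blocks=blocks,
                       span=(head.line, head.col))

    @staticmethod
    def _singleton_kind(block: A.Block) -> Optional[str]:
        if isinstance(block, A.DeclarationsBlock):
            return block.kind
        if isinstance(block, A.EquationsBlock):
            return "equations"
        if isinstance(block, A.InputBlock):
            return "input"
        if isinstance(block, A.OutputBlock):
            return "output"
        if isinstance(block, A.UpdateBlock):
            return "update"
        return None

    def _parse_block(self) -> A.Block:
        tok = self._peek()
        if tok.type != NAME:
            raise self._fail("expected a block keyword")
        kw = tok.value
        if kw in ("state", "parameters", "internals"):
            return self._parse_decl_block(kw)
        if kw == "equations":
            return self._parse_equations_block()
        if kw == "input":
            return self._parse_input_block()
        if kw == "output":
            return self._parse_output_block()
        if kw == "update":
            span = (tok.line, tok.col)
            self._advance()
            self._expect(OP, ":")
            return A.UpdateBlock(statements=self._parse_suite(), span=span)
        if kw == "onReceive":
            return self._parse_on_receive()
        if kw == "onCondition":
            return self._parse_on_condition()
        if kw == "function":
            return self._parse_function()
        raise self._fail(f"unknown block keyword {kw!r}")

    def _parse_decl_block(self, kind: str) -> A.DeclarationsBlock:
        tok = self._advance()
        self._expect(OP, ":")
        self._expect(NEWLINE)
        self._expect(INDENT)
        self._skip_newlines()
        decls = []
        while not self._at(DEDENT):
            decls.append(self._parse_declaration())
            self._skip_newlines()
        self._advance()  # DEDENT
        return A.DeclarationsBlock(kind=kind, declarations=decls,
                                   span=(tok.line, tok.col))

    def _collect_type_text(self, stop_values: tuple[str, ...]) -> str:
        """Greedily collect a type annotation as text, up to a stop token."""
        parts: list[str] = []
        depth = 0
        while True:
            tok = self._peek(skip_comments=False)
            if tok.type in (NEWLINE, COMMENT, EOF):
                break
            if tok.type == OP and depth == 0 and tok.value in stop_values:
                break
            if tok.type == OP and tok.value == "(":
                depth += 1
            elif tok.type == OP and tok.value == ")":
                if depth == 0:
                    break
                depth -= 1
            if tok.type not in (NAME, NUMBER, OP):
                break
            parts.append(tok.value)
            self._advance(skip_comments=False)
        if not parts:
            raise self._fail("expected a type annotation")
        return "".join(parts)

    def _parse_declaration(self) -> A.Declaration:
        name_tok = self._expect(NAME)
        type_text = self._collect_type_text(("=", "[", "<-"))
        size = None
        if self._at(OP, "["):
            self._advance()
            size_tok = self._advance()
            if size_tok.type == NUMBER:
                size = int(size_tok.value)
            elif size_tok.type == NAME:
                size = size_tok.value
            else:
                raise self._fail("vector size must be an integer literal or a name")
            self._expect(OP, "]")
        init = None
        if self._at(OP, "="):
            self._advance()
            init = self._parse_expression()
        doc = self._trailing_comment()
        self._expect(NEWLINE)
        return A.Declaration(name=name_tok.value, declared_type=type_text,
                             size=size, initializer=init, doc_comment=doc,
                             span=(name_tok.line, name_tok.col))

    def _parse_equations_block(self) -> A.EquationsBlock:
        tok = self._advance()
        self._expect(OP, ":")
        self._expect(NEWLINE)
        self._expect(INDENT)
        self._skip_newlines()
        items: list = []
        while not self._at(DEDENT):
            items.append(self._parse_equation_item())
            self._skip_newlines()
        self._advance()
        return A.EquationsBlock(items=items, span=(tok.line, tok.col))

    def _parse_equation_item(self):
        tok = self._peek()
        if tok.type == NAME and tok.value == "kernel":
            self._advance()
            name = self._expect(NAME).value
            self._expect(OP, "=")
            expr = self._parse_expression()
            self._trailing_comment()
            self._expect(NEWLINE)
            return A.KernelDef(name=name, expression=expr, span=(tok.line, tok.col))
        if tok.type == NAME and tok.value == "inline":
            self._advance()
            name = self._expect(NAME).value
            type_text = self._collect_type_text(("=",))
            self._expect(OP, "=")
            expr = self._parse_expression()
            self._trailing_comment()
            self._expect(NEWLINE)
            return A.InlineDef(name=name, declared_type=type_text,
                               expression=expr, span=(tok.line, tok.col))
        name_tok = self._expect(NAME)
        base = name_tok.value.rstrip("'")
        order = len(name_tok.value) - len(base)
        if order < 1:
            raise error("syntax",
                        f"equation left-hand side {name_tok.value!r} needs at "
                        "least one derivative prime",
                        (name_tok.line, name_tok.col), self.origin)
        self._expect(OP, "=")
        rhs = self._parse_expression()
        self._trailing_comment()
        self._expect(NEWLINE)
        return A.Equation(lhs_variable=base, order=order, rhs=rhs,
                          span=(name_tok.line, name_tok.col))

    def _parse_input_block(self) -> A.InputBlock:
        tok = self._advance()
        self._expect(OP, ":")
        self._expect(NEWLINE)
        self._expect(INDENT)
        self._skip_newlines()
        ports = []
        while not self._at(DEDENT):
            name_tok = self._expect(NAME)
            unit = None
            if not self._at(OP, "<-"):
                unit = self._collect_type_text(("<-",))
            self._expect(OP, "<-")
            kind_tok = self._expect(NAME)
            if kind_tok.value not in ("spike", "continuous"):
                raise error("syntax",
                            f"input port kind must be 'spike' or 'continuous', "
                            f"found {kind_tok.value!r}",
                            (kind_tok.line, kind_tok.col), self.origin)
            self._trailing_comment()
            self._expect(NEWLINE)
            ports.append(A.InputPort(name=name_tok.value, kind=kind_tok.value,
                                     declared_unit=unit,
                                     span=(name_tok.line, name_tok.col)))
            self._skip_newlines()
        self._advance()
        return A.InputBlock(ports=ports, span=(tok.line, tok.col))

    def _parse_output_block(self) -> A.OutputBlock:
        tok = self._advance()
        self._expect(OP, ":")
        self._expect(NEWLINE)
        self._expect(INDENT)
        self._skip_newlines()
        kind_tok = self._expect(NAME)
        if kind_tok.value not in ("spike", "continuous"):
            raise error("syntax", "output kind must be 'spike' or 'continuous'",
                        (kind_tok.line, kind_tok.col), self.origin)
        self._expect(NEWLINE)
        self._skip_newlines()
        self._expect(DEDENT)
        return A.OutputBlock(kind=kind_tok.value, span=(tok.line, tok.col))

    def _parse_on_receive(self) -> A.OnReceive:
        tok = self._advance()
        self._expect(OP, "(")
        port = self._expect(NAME).value
        priority = None
        if self._at(OP, ","):
            self._advance()
            self._expect(NAME, "priority")
            self._expect(OP, "=")
            sign = 1
            if self._at(OP, "-"):
                self._advance()
                sign = -1
            prio_tok = self._expect(NUMBER)
            if "." in prio_tok.value or "e" in prio_tok.value.lower():
                raise error("syntax", "priority must be an integer",
                            (prio_tok.line, prio_tok.col), self.origin)
            priority = sign * int(prio_tok.value)
        self._expect(OP, ")")
        self._expect(OP, ":")
        return A.OnReceive(port=port, priority=priority,
                           statements=self._parse_suite(), span=(tok.line, tok.col))

    def _parse_on_condition(self) -> A.OnCondition:
        tok = self._advance()
        self._expect(OP, "(")
        cond = self._parse_expression()
        self._expect(OP, ")")
        self._expect(OP, ":")
        return A.OnCondition(condition=cond, statements=self._parse_suite(),
                             span=(tok.line, tok.col))

    def _parse_function(self) -> A.FunctionDef:
        tok = self._advance()
        name = self._expect(NAME).value
        self._expect(OP, "(")
        params: list[tuple[str, str]] = []
        while not self._at(OP, ")"):
            pname = self._expect(NAME).value
            ptype = self._collect_type_text((",", ")"))
            params.append((pname, ptype))
            if self._at(OP, ","):
                self._advance()
        self._expect(OP, ")")
        return_type = None
        if not self._at(OP, ":"):
            return_type = self._collect_type_text((":",))
        self._expect(OP, ":")
        return A.FunctionDef(name=name, params=params, return_type=return_type,
                             statements=self._parse_suite(), span=(tok.line, tok.col))

    # -- statements ----------------------------------------------------------

    def _parse_suite(self) -> list[A.Statement]:
        self._expect(NEWLINE)
        self._expect(INDENT)
        self._skip_newlines()
        stmts = []
        while not self._at(DEDENT):
            stmts.append(self._parse_statement())
            self._skip_newlines()
        self._advance()
        return stmts

    def _parse_statement(self) -> A.Statement:
        tok = self._peek()
        if tok.type != NAME:
            raise self._fail("expected a statement")
        kw = tok.value
        if kw == "if":
            return self._parse_if()
        if kw == "while":
            self._advance()
            cond = self._parse_expression()
            self._expect(OP, ":")
            return A.WhileStmt(condition=cond, body=self._parse_suite(),
                               span=(tok.line, tok.col))
        if kw == "for":
            return self._parse_for()
        if kw == "return":
            self._advance()
            value = None
            if not self._at(NEWLINE):
                value = self._parse_expression()
            self._trailing_comment()
            self._expect(NEWLINE)
            return A.ReturnStmt(value=value, span=(tok.line, tok.col))

        # NAME-led small statement: call, assignment, or local declaration
        nxt = self.tokens[self._lookahead_index(1)]
        if nxt.type == OP and nxt.value == "(":
            expr = self._parse_expression()
            if not isinstance(expr, (A.FunctionCall,)):
                raise self._fail("expected a call statement")
            self._trailing_comment()
            self._expect(NEWLINE)
            return A.ExprStmt(call=expr, span=(tok.line, tok.col))
        if nxt.type == OP and (nxt.value in _ASSIGN_OPS or nxt.value == "["):
            return self._parse_assignment()
        if nxt.type in (NAME, NUMBER):
            decl = self._parse_declaration()
            return A.DeclarationStmt(declaration=decl, span=decl.span)
        raise self._fail("expected an assignment, declaration, or call")

    def _lookahead_index(self, n: int) -> int:
        pos = self.pos
        seen = 0
        while True:
            if self.tokens[pos].type != COMMENT:
                if seen == n:
                    return pos
                seen += 1
            pos += 1

    def _parse_if(self) -> A.IfStmt:
        tok = self._advance()  # 'if'
        branches = []
        cond = self._parse_expression()
        self._expect(OP, ":")
        branches.append((cond, self._parse_suite()))
        while self._at(NAME, "elif"):
            self._advance()
            cond = self._parse_expression()
            self._expect(OP, ":")
            branches.append((cond, self._parse_suite()))
        if self._at(NAME, "else"):
            self._advance()
            self._expect(OP, ":")
            branches.append((None, self._parse_suite()))
        return A.IfStmt(branches=branches, span=(tok.line, tok.col))

    def _parse_for(self) -> A.ForStmt:
        tok = self._advance()  # 'for'
        var = self._expect(NAME).value
        self._expect(NAME, "in")
        start = self._parse_expression()
        self._expect(OP, "...")
        stop = self._parse_expression()
        step = None
        if self._at(NAME, "step"):
            self._advance()
            step = self._parse_expression()
        self._expect(OP, ":")
        return A.ForStmt(var=var, start=start, stop=stop, step=step,
                         body=self._parse_suite(), span=(tok.line, tok.col))

    def _parse_assignment(self) -> A.Assignment:
        name_tok = self._expect(NAME)
        index = None
        if self._at(OP, "["):
            self._advance()
            index = self._parse_expression()
            self._expect(OP, "]")
        op_tok = self._advance()
        if op_tok.type != OP or op_tok.value not in _ASSIGN_OPS:
            raise error("syntax", f"expected an assignment operator, found {op_tok}",
                        (op_tok.line, op_tok.col), self.origin)
        value = self._parse_expression()
        self._trailing_comment()
        self._expect(NEWLINE)
        target = A.VarRef(name=name_tok.value, index=index,
                          span=(name_tok.line, name_tok.col))
        return A.Assignment(target=target, op=op_tok.value, value=value,
                            span=(name_tok.line, name_tok.col))

    # -- expressions ---------------------------------------------------------

    def _parse_expression(self) -> A.Expression:
        return self._parse_or()

    def _parse_or(self) -> A.Expression:
        left = self._parse_and()
        while self._at(NAME, "or"):
            tok = self._advance()
            right = self._parse_and()
            left = A.BinaryOp(op="or", left=left, right=right, span=(tok.line, tok.col))
        return left

    def _parse_and(self) -> A.Expression:
        left = self._parse_not()
        while self._at(NAME, "and"):
            tok = self._advance()
            right = self._parse_not()
            left = A.BinaryOp(op="and", left=left, right=right, span=(tok.line, tok.col))
        return left

    def _parse_not(self) -> A.Expression:
        if self._at(NAME, "not"):
            tok = self._advance()
            return A.UnaryOp(op="not", operand=self._parse_not(), span=(tok.line, tok.col))
        return self._parse_comparison()

    def _parse_comparison(self) -> A.Expression:
        left = self._parse_arith()
        tok = self._peek()
        if tok.type == OP and tok.value in _CMP_OPS:
            self._advance()
            right = self._parse_arith()
            return A.BinaryOp(op=tok.value, left=left, right=right,
                              span=(tok.line, tok.col))
        return left

    def _parse_arith(self) -> A.Expression:
        left = self._parse_term()
        while self._at(OP, "+") or self._at(OP, "-"):
            tok = self._advance()
            right = self._parse_term()
            left = A.BinaryOp(op=tok.value, left=left, right=right,
                              span=(tok.line, tok.col))
        return left

    def _parse_term(self) -> A.Expression:
        left = self._parse_unary()
        while self._at(OP, "*") or self._at(OP, "/"):
            tok = self._advance()
            right = self._parse_unary()
            left = A.BinaryOp(op=tok.value, left=left, right=right,
                              span=(tok.line, tok.col))
        return left

    def _parse_unary(self) -> A.Expression:
        if self._at(OP, "-") or self._at(OP, "+"):
            tok = self._advance()
            return A.UnaryOp(op=tok.value, operand=self._parse_unary(),
                             span=(tok.line, tok.col))
        return self._parse_power()

    def _parse_power(self) -> A.Expression:
        base = self._parse_primary()
        if self._at(OP, "**"):
            tok = self._advance()
            exponent = self._parse_unary()  # right-associative, allows -2
            return A.BinaryOp(op="**", left=base, right=exponent,
                              span=(tok.line, tok.col))
        return base

    def _parse_primary(self) -> A.Expression:
        tok = self._peek()
        if tok.type == NUMBER:
            self._advance()
            is_int = "." not in tok.value and "e" not in tok.value.lower()
            value = int(tok.value) if is_int else float(tok.value)
            unit = None
            nxt = self._peek()
            if nxt.type == NAME and nxt.value not in KEYWORDS:
                unit = self._advance().value
            return A.NumberLiteral(value=float(value), is_int=is_int, unit=unit,
                                   span=(tok.line, tok.col))
        if tok.type == STRING:
            self._advance()
            return A.StringLiteral(value=tok.value, span=(tok.line, tok.col))
        if tok.type == NAME and tok.value in ("true", "false"):
            self._advance()
            return A.BooleanLiteral(value=(tok.value == "true"), span=(tok.line, tok.col))
        if tok.type == NAME:
            self._advance()
            if self._at(OP, "("):
                return self._finish_call(tok)
            if self._at(OP, "["):
                self._advance()
                index = self._parse_expression()
                self._expect(OP, "]")
                return A.VarRef(name=tok.value, index=index, span=(tok.line, tok.col))
            return A.VarRef(name=tok.value, span=(tok.line, tok.col))
        if tok.type == OP and tok.value == "(":
            self._advance()
            expr = self._parse_expression()
            self._expect(OP, ")")
            return expr
        raise self._fail("expected an expression")

    def _finish_call(self, name_tok: Token) -> A.Expression:
        self._expect(OP, "(")
        args: list[A.Expression] = []
        while not self._at(OP, ")"):
            args.append(self._parse_expression())
            if self._at(OP, ","):
                self._advance()
            elif not self._at(OP, ")"):
                raise self._fail("expected ',' or ')' in argument list")
        self._expect(OP, ")")
        span = (name_tok.line, name_tok.col)
        if name_tok.value == "convolve":
            if len(args) != 2 or not all(
                    isinstance(a, A.VarRef) and a.index is None for a in args):
                raise error("syntax",
                            "convolve takes exactly one kernel name and one "
                            "spike-port name", span, self.origin)
            return A.Convolve(kernel=args[0].name, port=args[1].name, span=span)
        return A.FunctionCall(name=name_tok.value, args=args, span=span)


def parse_model(text: str, origin: str = "<memory>") -> A.Model:
    """Parse model source text into an AST."""
    return Parser(tokenize(text, origin), origin).parse_model()
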