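"""Tokenizer for the indentation-based model syntax.

Produces a flat token list with 1-based (line, column) positions.  Layout is
significant: indentation changes yield INDENT/DEDENT tokens and logical line
ends yield NEWLINE, in the style of the Python tokenizer.  ``#`` starts a
comment token; comments and blank lines do not affect indentation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diagnostics import error

# token types
NAME = "NAME"
NUMBER = "NUMBER"
STRING = "STRING"
OP = "OP"
NEWLINE = "NEWLINE"
INDENT = "INDENT"
DEDENT = "DEDENT"
COMMENT = "COMMENT"
EOF = "EOF"

KEYWORDS = frozenset({
    "model", "state", "parameters", "internals", "equations", "input",
    "output", "update", "onReceive", "onCondition", "function", "kernel",
    "inline", "if", "elif", "else", "while", "for", "in", "step", "return",
    "and", "or", "not", "true", "false", "spike", "continuous", "priority",
})

_MULTI_OPS = ("...", "**", "==", "!=", "<=", ">=", "+=", "-=", "*=", "/=", "<-")
_SINGLE_OPS = "=+-*/()[]:,<>."


@dataclass(frozen=True)
class Token:
    type: str
    value: str
    line: int
    col: int

    def __repr__(self) -> str:  # compact, used in syntax-error messages
        return f"{self.type}({self.value!r})@{self.line}:{self.col}"


class Lexer:
    def __init__(self, text: str, origin: str = "<memory>"):
        self.text = text
        self.origin = origin

    def tokenize(self) -> list[Token]:
        tokens: list[Token] = []
        indents = [0]
        lines = self.text.split("\n")
        paren_depth = 0
        in_docstring: list[str] | None = None
        doc_start = (0, 0)

        for lineno, raw in enumerate(lines, start=1):
            if in_docstring is not None:
                # inside a multi-line triple-quoted string
                end = raw.find('"""')
                if end < 0:
                    in_docstring.append(raw)
                    continue
                in_docstring.append(raw[:end])
                tokens.append(Token(STRING, "\n".join(in_docstring),
                                    doc_start[0], doc_start[1]))
                in_docstring = None
                rest = raw[end + 3:]
                self._lex_code(rest, lineno, end + 4, tokens)
                if paren_depth == 0:
                    tokens.append(Token(NEWLINE, "", lineno, len(raw) + 1))
                continue

            stripped = raw.strip()
            if paren_depth == 0:
                if not stripped:
                    continue  # blank line: no layout effect
                indent = len(raw) - len(raw.lstrip(" "))
                if raw[:indent].find("\t") >= 0 or (raw.lstrip(" ")[:1] == "\t"):
                    raise error("lex-tab", "tab characters are not allowed in indentation",
                                (lineno, 1), self.origin)
                if stripped.startswith("#"):
                    tokens.append(Token(COMMENT, stripped[1:].strip(), lineno, indent + 1))
                    continue  # comment-only line: no layout effect
                if indent > indents[-1]:
                    indents.append(indent)
                    tokens.append(Token(INDENT, "", lineno, 1))
                while indent < indents[-1]:
                    indents.pop()
                    tokens.append(Token(DEDENT, "", lineno, 1))
                if indent != indents[-1]:
                    raise error("lex-indent", "inconsistent dedent", (lineno, 1), self.origin)

            before = len(tokens)
            opened = self._lex_code(raw, lineno, 1, tokens)
            paren_depth += opened
            if paren_depth < 0:
                raise error("lex-paren", "unbalanced closing bracket",
                            (lineno, 1), self.origin)
            # a line holding an unterminated triple-quoted string?
            if tokens and tokens[-1].type == STRING and tokens[-1].value == "\x00OPEN":
                tok = tokens.pop()
                in_docstring = [raw[raw.find('"""') + 3:]]
                doc_start = (tok.line, tok.col)
                continue
            if paren_depth == 0 and len(tokens) > before:
                tokens.append(Token(NEWLINE, "", lineno, len(raw) + 1))

        if in_docstring is not None:
            raise error("lex-string", "unterminated docstring", doc_start, self.origin)
        while len(indents) > 1:
            indents.pop()
            tokens.append(Token(DEDENT, "", len(lines), 1))
        tokens.append(Token(EOF, "", len(lines), 1))
        return tokens

    def _lex_code(self, line: str, lineno: int, startcol: int, tokens: list[Token]) -> int:
        """Lex the code portion of one physical line; returns net bracket depth."""
        i = startcol - 1
        opened = 0
        n = len(line)
        while i < n:
            c = line[i]
            col = i + 1
            if c in " \t":
                i += 1
                continue
            if c == "#":
                tokens.append(Token(COMMENT, line[i + 1:].strip(), lineno, col))
                return opened
            if line.startswith('"""', i):
                end = line.find('"""', i + 3)
                if end < 0:
                    # continues on following lines; sentinel resolved by caller
                    tokens.append(Token(STRING, "\x00OPEN", lineno, col))
                    return opened
                tokens.append(Token(STRING, line[i + 3:end], lineno, col))
                i = end + 3
                continue
            if c == '"':
                end = line.find('"', i + 1)
                if end < 0:
                    raise error("lex-string", "unterminated string literal",
                                (lineno, col), self.origin)
                tokens.append(Token(STRING, line[i + 1:end], lineno, col))
                i = end + 1
                continue
            if c.isalpha() or c == "_":
                j = i
                while j < n and (line[j].isalnum() or line[j] == "_"):
                    j += 1
                while j < n and line[j] == "'":  # derivative primes are part of the name
                    j += 1
                tokens.append(Token(NAME, line[i:j], lineno, col))
                i = j
                continue
            if c.isdigit() or (c == "." and i + 1 < n and line[i + 1].isdigit()):
                j = i
                while j < n and line[j].isdigit():
                    j += 1
                if j < n and line[j] == "." and not line.startswith("...", j):
                    j += 1
                    while j < n and line[j].isdigit():
                        j += 1
                if j < n and line[j] in "eE":
                    k = j + 1
                    if k < n and line[k] in "+-":
                        k += 1
                    if k < n and line[k].isdigit():
                        j = k
                        while j < n and line[j].isdigit():
                            j += 1
                tokens.append(Token(NUMBER, line[i:j], lineno, col))
                i = j
                continue
            matched = False
            for op in _MULTI_OPS:
                if line.startswith(op, i):
                    tokens.append(Token(OP, op, lineno, col))
                    i += len(op)
                    matched = True
                    break
            if matched:
                continue
            if c in _SINGLE_OPS:
                if c in "([":
                    opened += 1
                elif c in ")]":
                    opened -= 1
                tokens.append(Token(OP, c, lineno, col))
                i += 1
                continue
            raise error("lex-illegal", f"illegal character {c!r}", (lineno, col), self.origin)
        return opened


def tokenize(text: str, origin: str = "<memory>") -> list[Token]:
    """Tokenize model source text into a flat, position-annotated token list."""
    return Lexer(text, origin).tokenize()
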