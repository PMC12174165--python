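"""Physical-unit algebra and the static type universe of the language.

Quantities are typed by a :class:`Dimension` (integer exponents over the seven
SI base dimensions) plus a decadic *scale*: the integer power of ten relating
the unit to the coherent SI unit of the same dimension.  ``mV`` is the volt
dimension at scale -3; ``nS`` is the siemens dimension at scale -9.  Two
quantities are addition-compatible iff their dimensions are equal, and the
factor converting a magnitude from one to the other is ``10**(scale_a -
scale_b)``.  Scales are restricted to integer powers of ten (prefixed SI units
only); offset units such as degrees Celsius are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


class UnitError(ValueError):
    """Raised for unknown unit names or dimensionally incompatible operations."""


# SI base dimension order: length, mass, time, current, temperature,
# amount of substance, luminous intensity.
_NDIM = 7


@dataclass(frozen=True)
class Dimension:
    """Integer exponents over the 7 SI base dimensions."""

    exponents: tuple[int, int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.exponents) != _NDIM:
            raise ValueError("dimension needs exactly 7 exponents")

    @property
    def is_dimensionless(self) -> bool:
        return all(e == 0 for e in self.exponents)

    def __mul__(self, other: "Dimension") -> "Dimension":
        return Dimension(tuple(a + b for a, b in zip(self.exponents, other.exponents)))

    def __truediv__(self, other: "Dimension") -> "Dimension":
        return Dimension(tuple(a - b for a, b in zip(self.exponents, other.exponents)))

    def __pow__(self, k: int) -> "Dimension":
        return Dimension(tuple(a * k for a in self.exponents))


DIMENSIONLESS = Dimension((0,) * 7)
LENGTH = Dimension((1, 0, 0, 0, 0, 0, 0))
MASS = Dimension((0, 1, 0, 0, 0, 0, 0))
TIME = Dimension((0, 0, 1, 0, 0, 0, 0))
CURRENT = Dimension((0, 0, 0, 1, 0, 0, 0))
TEMPERATURE = Dimension((0, 0, 0, 0, 1, 0, 0))
AMOUNT = Dimension((0, 0, 0, 0, 0, 1, 0))
LUMINOSITY = Dimension((0, 0, 0, 0, 0, 0, 1))


@dataclass(frozen=True)
class QuantityType:
    """A dimension plus a decadic scale relative to the coherent SI unit."""

    dimension: Dimension
    scale: int = 0

    def __mul__(self, other: "QuantityType") -> "QuantityType":
        return QuantityType(self.dimension * other.dimension, self.scale + other.scale)

    def __truediv__(self, other: "QuantityType") -> "QuantityType":
        return QuantityType(self.dimension / other.dimension, self.scale - other.scale)

    def __pow__(self, k: int) -> "QuantityType":
        return QuantityType(self.dimension ** k, self.scale * k)


def conversion_factor(from_q: QuantityType, to_q: QuantityType) -> float:
    """Factor expressing a magnitude given in ``from_q`` units in ``to_q`` units.

    ``conversion_factor(mV, V) == 1e-3``: 1 mV is 10^-3 V.  Raises
    :class:`UnitError` when the dimensions differ.
    """
    if from_q.dimension != to_q.dimension:
        raise UnitError(
            f"incompatible units: dimensions {from_q.dimension.exponents} "
            f"and {to_q.dimension.exponents} differ"
        )
    return 10.0 ** (from_q.scale - to_q.scale)


# -- named units ------------------------------------------------------------

# Derived units carry their dimension and the scale of the *coherent* unit
# (all zero except the gram, which sits at 10^-3 kg).
_BASE_UNITS: dict[str, QuantityType] = {
    "m": QuantityType(LENGTH, 0),
    "g": QuantityType(MASS, -3),  # SI coherent mass unit is the kilogram
    "s": QuantityType(TIME, 0),
    "A": QuantityType(CURRENT, 0),
    "K": QuantityType(TEMPERATURE, 0),
    "mol": QuantityType(AMOUNT, 0),
    "cd": QuantityType(LUMINOSITY, 0),
    # derived
    "Hz": QuantityType(TIME ** -1, 0),
    "V": QuantityType(Dimension((2, 1, -3, -1, 0, 0, 0)), 0),
    "Ohm": QuantityType(Dimension((2, 1, -3, -2, 0, 0, 0)), 0),
    "S": QuantityType(Dimension((-2, -1, 3, 2, 0, 0, 0)), 0),
    "F": QuantityType(Dimension((-2, -1, 4, 2, 0, 0, 0)), 0),
    "C": QuantityType(Dimension((0, 0, 1, 1, 0, 0, 0)), 0),
    "J": QuantityType(Dimension((2, 1, -2, 0, 0, 0, 0)), 0),
    "W": QuantityType(Dimension((2, 1, -3, 0, 0, 0, 0)), 0),
    "N": QuantityType(Dimension((1, 1, -2, 0, 0, 0, 0)), 0),
}

_PREFIXES: dict[str, int] = {
    "f": -15,
    "p": -12,
    "n": -9,
    "u": -6,
    "mu": -6,
    "m": -3,
    "c": -2,
    "d": -1,
    "da": 1,
    "h": 2,
    "k": 3,
    "M": 6,
    "G": 9,
    "T": 12,
}


def resolve_unit_name(name: str) -> Optional[QuantityType]:
    """Resolve a single (possibly prefixed) unit name, or None if unknown.

    Bare unit names resolve before prefixed interpretations, so ``mol`` is the
    mole, not milli-anything.
    """
    if name in _BASE_UNITS:
        return _BASE_UNITS[name]
    # longest prefixes first so that "da" beats "d"
    for prefix in sorted(_PREFIXES, key=len, reverse=True):
        if name.startswith(prefix) and name[len(prefix):] in _BASE_UNITS:
            base = _BASE_UNITS[name[len(prefix):]]
            return QuantityType(base.dimension, base.scale + _PREFIXES[prefix])
    return None


def is_unit_name(name: str) -> bool:
    return resolve_unit_name(name) is not None


# -- unit-expression parsing ------------------------------------------------

class _UnitExprParser:
    """Products, quotients and integer powers of prefixed unit names.

    Grammar: expr := term (('*'|'/') term)* ; term := factor ('**' sint)? ;
    factor := NAME | '1' | '(' expr ')'.  The literal ``1`` supports
    reciprocal units such as ``1/s``.
    """

    def __init__(self, text: str):
        self.text = text
        self.tokens = self._lex(text)
        self.pos = 0

    @staticmethod
    def _lex(text: str) -> list[str]:
        tokens: list[str] = []
        i = 0
        while i < len(text):
            c = text[i]
            if c.isspace():
                i += 1
            elif c.isalpha() or c == "_":
                j = i
                while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                    j += 1
                tokens.append(text[i:j])
                i = j
            elif text.startswith("**", i):
                tokens.append("**")
                i += 2
            elif c in "*/()":
                tokens.append(c)
                i += 1
            elif c.isdigit() or c in "+-":
                j = i + 1
                while j < len(text) and text[j].isdigit():
                    j += 1
                tokens.append(text[i:j])
                i = j
            else:
                raise UnitError(f"illegal character {c!r} in unit expression {text!r}")
        return tokens

    def _peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise UnitError(f"unexpected end of unit expression {self.text!r}")
        self.pos += 1
        return tok

    def parse(self) -> QuantityType:
        q = self._expr()
        if self._peek() is not None:
            raise UnitError(f"trailing tokens in unit expression {self.text!r}")
        return q

    def _expr(self) -> QuantityType:
        q = self._term()
        while self._peek() in ("*", "/"):
            op = self._next()
            rhs = self._term()
            q = q * rhs if op == "*" else q / rhs
        return q

    def _term(self) -> QuantityType:
        q = self._factor()
        if self._peek() == "**":
            self._next()
            exp_tok = self._next()
            try:
                k = int(exp_tok)
            except ValueError:
                raise UnitError(f"non-integer exponent {exp_tok!r} in {self.text!r}")
            q = q ** k
        return q

    def _factor(self) -> QuantityType:
        tok = self._next()
        if tok == "(":
            q = self._expr()
            if self._next() != ")":
                raise UnitError(f"unbalanced parentheses in {self.text!r}")
            return q
        if tok == "1":
            return QuantityType(DIMENSIONLESS, 0)
        q = resolve_unit_name(tok)
        if q is None:
            raise UnitError(f"unknown unit name {tok!r} in {self.text!r}")
        return q


def parse_unit(text: str) -> QuantityType:
    """Parse a unit expression such as ``mV``, ``s**-1`` or ``mV*nS``."""
    return _UnitExprParser(text).parse()


# -- the type universe ------------------------------------------------------

@dataclass(frozen=True)
class TypeDesc:
    """One of the scalar kinds of the language; quantities carry their unit."""

    kind: str  # integer | real | boolean | string | void | quantity
    quantity: Optional[QuantityType] = None

    def __post_init__(self) -> None:
        if self.kind == "quantity" and self.quantity is None:
            raise ValueError("quantity TypeDesc needs a QuantityType")
        if self.kind != "quantity" and self.quantity is not None:
            raise ValueError(f"{self.kind} TypeDesc must not carry a unit")

    @property
    def is_numeric(self) -> bool:
        return self.kind in ("integer", "real", "quantity")

    def __str__(self) -> str:
        if self.kind == "quantity":
            return f"quantity[dim={self.quantity.dimension.exponents}, scale={self.quantity.scale}]"
        return self.kind


INTEGER = TypeDesc("integer")
REAL = TypeDesc("real")
BOOLEAN = TypeDesc("boolean")
STRING = TypeDesc("string")
VOID = TypeDesc("void")


def quantity(q: QuantityType) -> TypeDesc:
    return TypeDesc("quantity", q)


def parse_type(text: str) -> TypeDesc:
    """Resolve a declared-type annotation: builtin kind or unit expression."""
    stripped = text.strip()
    builtin = {"integer": INTEGER, "real": REAL, "boolean": BOOLEAN,
               "string": STRING, "void": VOID}
    if stripped in builtin:
        return builtin[stripped]
    return quantity(parse_unit(stripped))


# time in ms is the ambient unit of the simulation clock and of the
# predefined variable t
MS = parse_unit("ms")
PER_SECOND = QuantityType(TIME ** -1, 0)
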