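"""Arithmetic/boolean expression language used in Dynamics blocks.

Value strings such as ``"y - a*x^3 + b*x^2"`` or condition tests such as
``"v .gt. 0 .and. spiking .lt. 0.5"`` are parsed into small trees which
can then be dimension-checked against a symbol→dimension scope and
evaluated against a symbol→value scope.  Both the symbolic comparison
operators (``> < >= <= = !=``) and the dotted dialect (``.gt. .lt.
.geq. .leq. .eq. .neq. .and. .or.``) are accepted and normalised to one
internal form.

Precedence, loosest to tightest: ``or`` < ``and`` < ``not`` <
comparisons < ``+ -`` < ``* /`` < unary minus < ``^`` (right
associative).  Booleans are represented numerically (1.0 / 0.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Optional

from .dimensions import DIMENSIONLESS, Dimension, DimensionError

__all__ = [
    "Expr",
    "Lit",
    "Sym",
    "Un",
    "Bin",
    "Call",
    "ExpressionError",
    "parse_expr",
    "serialize_expr",
    "infer_dimension",
    "evaluate",
    "compile_expr",
    "free_symbols",
    "FUNCTIONS",
]


class ExpressionError(ValueError):
    """Syntax error (with position) or unknown function/operator."""


@dataclass(frozen=True)
class Lit:
    value: float


@dataclass(frozen=True)
class Sym:
    name: str


@dataclass(frozen=True)
class Un:
    op: str  # "neg" | "not"
    operand: "Expr"


@dataclass(frozen=True)
class Bin:
    op: str  # + - * / ^ > < >= <= == != and or
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple["Expr", ...]


Expr = Lit | Sym | Un | Bin | Call

#: Function library: name -> (arity, float implementation).  ``random(x)``
#: draws uniformly on [0, x) from the simulation RNG and is handled
#: separately so evaluation stays deterministic under a fixed seed.
FUNCTIONS: dict[str, tuple[int, Optional[Callable[..., float]]]] = {
    "exp": (1, math.exp),
    "ln": (1, math.log),
    "log": (1, math.log),  # natural log, LEMS convention
    "sqrt": (1, math.sqrt),
    "sin": (1, math.sin),
    "cos": (1, math.cos),
    "tanh": (1, math.tanh),
    "abs": (1, abs),
    "ceil": (1, math.ceil),
    "floor": (1, math.floor),
    "random": (1, None),
}

_DOTTED = {
    ".gt.": ">",
    ".lt.": "<",
    ".geq.": ">=",
    ".leq.": "<=",
    ".eq.": "==",
    ".neq.": "!=",
    ".and.": "and",
    ".or.": "or",
}


@dataclass
class _Token:
    kind: str  # num | name | op | lparen | rparen | comma | end
    text: str
    pos: int


def _tokenize(text: str) -> Iterator[_Token]:
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c == "." and i + 1 < n and text[i + 1].isalpha():
            j = text.find(".", i + 1)
            word = text[i : j + 1] if j != -1 else ""
            if word in _DOTTED:
                yield _Token("op", _DOTTED[word], i)
                i = j + 1
                continue
            raise ExpressionError(f"unknown dotted operator at position {i}: {text[i:i+6]!r}")
        if c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()):
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            if j < n and text[j] in "eE":
                k = j + 1
                if k < n and text[k] in "+-":
                    k += 1
                if k < n and text[k].isdigit():
                    j = k
                    while j < n and text[j].isdigit():
                        j += 1
            word = text[i:j]
            try:
                float(word)
            except ValueError:
                raise ExpressionError(
                    f"malformed number {word!r} at position {i}"
                ) from None
            yield _Token("num", word, i)
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            word = text[i:j]
            if word in ("and", "or", "not"):
                yield _Token("op", word, i)
            else:
                yield _Token("name", word, i)
            i = j
            continue
        for two in (">=", "<=", "==", "!=", "<>"):
            if text.startswith(two, i):
                yield _Token("op", "!=" if two == "<>" else two, i)
                i += 2
                break
        else:
            if c in "+-*/^><(),=":
                if c == "(":
                    yield _Token("lparen", c, i)
                elif c == ")":
                    yield _Token("rparen", c, i)
                elif c == ",":
                    yield _Token("comma", c, i)
                elif c == "=":
                    yield _Token("op", "==", i)
                else:
                    yield _Token("op", c, i)
                i += 1
            else:
                raise ExpressionError(f"unexpected character {c!r} at position {i}")
    yield _Token("end", "", n)


# binding powers: (left, right); right < left for right-associative ops
_BIN_BP = {
    "or": (1, 2),
    "and": (3, 4),
    ">": (7, 8),
    "<": (7, 8),
    ">=": (7, 8),
    "<=": (7, 8),
    "==": (7, 8),
    "!=": (7, 8),
    "+": (9, 10),
    "-": (9, 10),
    "*": (11, 12),
    "/": (11, 12),
    "^": (16, 15),
}
_NOT_BP = 5
_NEG_BP = 13


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.advance()
        if tok.kind != kind:
            raise ExpressionError(
                f"expected {kind} at position {tok.pos}, got {tok.text!r}"
            )
        return tok

    def parse(self) -> Expr:
        e = self.expr(0)
        tok = self.peek()
        if tok.kind != "end":
            raise ExpressionError(
                f"unexpected trailing input at position {tok.pos}: {tok.text!r}"
            )
        return e

    def expr(self, min_bp: int) -> Expr:
        tok = self.advance()
        if tok.kind == "num":
            left: Expr = Lit(float(tok.text))
        elif tok.kind == "name":
            if self.peek().kind == "lparen":
                left = self.call(tok)
            else:
                left = Sym(tok.text)
        elif tok.kind == "lparen":
            left = self.expr(0)
            self.expect("rparen")
        elif tok.kind == "op" and tok.text == "-":
            left = Un("neg", self.expr(_NEG_BP))
        elif tok.kind == "op" and tok.text == "+":
            left = self.expr(_NEG_BP)
        elif tok.kind == "op" and tok.text == "not":
            left = Un("not", self.expr(_NOT_BP))
        else:
            raise ExpressionError(
                f"unexpected token {tok.text!r} at position {tok.pos}"
            )
        while True:
            tok = self.peek()
            if tok.kind != "op" or tok.text not in _BIN_BP:
                break
            lbp, rbp = _BIN_BP[tok.text]
            if lbp < min_bp:
                break
            self.advance()
            right = self.expr(rbp)
            left = Bin(tok.text, left, right)
        return left

    def call(self, name_tok: _Token) -> Expr:
        if name_tok.text not in FUNCTIONS:
            raise ExpressionError(
                f"unknown function {name_tok.text!r} at position {name_tok.pos}"
            )
        self.expect("lparen")
        args: list[Expr] = []
        if self.peek().kind != "rparen":
            args.append(self.expr(0))
            while self.peek().kind == "comma":
                self.advance()
                args.append(self.expr(0))
        self.expect("rparen")
        arity = FUNCTIONS[name_tok.text][0]
        if len(args) != arity:
            raise ExpressionError(
                f"function {name_tok.text!r} takes {arity} argument(s), "
                f"got {len(args)}"
            )
        return Call(name_tok.text, tuple(args))


def parse_expr(text: str) -> Expr:
    """Parse a value/condition string into an expression tree."""
    if not isinstance(text, str) or not text.strip():
        raise ExpressionError("empty expression")
    return _Parser(text).parse()


_SERIAL_OP = {"==": ".eq.", "!=": ".neq.", ">": ".gt.", "<": ".lt.",
              ">=": ".geq.", "<=": ".leq.", "and": ".and.", "or": ".or."}


def _prec(e: Expr) -> int:
    if isinstance(e, Bin):
        return _BIN_BP[e.op][0]
    if isinstance(e, Un):
        return _NEG_BP if e.op == "neg" else _NOT_BP
    return 100


def serialize_expr(e: Expr) -> str:
    """Canonical text form; ``parse_expr(serialize_expr(e))`` reproduces ``e``."""
    if isinstance(e, Lit):
        s = repr(e.value)
        return s[:-2] if s.endswith(".0") else s
    if isinstance(e, Sym):
        return e.name
    if isinstance(e, Un):
        inner = serialize_expr(e.operand)
        if _prec(e.operand) < _prec(e):
            inner = f"({inner})"
        return f"-{inner}" if e.op == "neg" else f"not {inner}"
    if isinstance(e, Call):
        return f"{e.func}({', '.join(serialize_expr(a) for a in e.args)})"
    assert isinstance(e, Bin)
    lbp, rbp = _BIN_BP[e.op]
    left = serialize_expr(e.left)
    right = serialize_expr(e.right)
    if _prec(e.left) < lbp or (
        e.op == "^" and isinstance(e.left, Bin) and e.left.op == "^"
    ):
        left = f"({left})"
    # parenthesise the right operand when it binds no tighter than required,
    # so left-assoc chains like a-(b-c) keep their grouping
    if _prec(e.right) < rbp or (
        isinstance(e.right, Bin) and _BIN_BP[e.right.op][0] == lbp and e.op != "^"
    ):
        right = f"({right})"
    op = _SERIAL_OP.get(e.op, e.op)
    return f"{left} {op} {right}"


class DimensionInconsistency(DimensionError):
    """Dimension check failure; carries the offending sub-expression."""

    def __init__(self, message: str, subexpr: Expr):
        super().__init__(f"{message} in {serialize_expr(subexpr)!r}")
        self.subexpr = subexpr


def _is_zero_literal(e: Expr) -> bool:
    return isinstance(e, Lit) and e.value == 0.0


def infer_dimension(e: Expr, scope: Mapping[str, Dimension]) -> Dimension:
    """Infer the dimension of ``e`` or raise :class:`DimensionInconsistency`.

    Rules: ``+``/``-`` and comparisons require equal operand dimensions
    (a literal ``0`` compares against any dimension — zero is
    scale-invariant); ``*``/``/`` combine exponent vectors; ``^``
    requires a dimensionless exponent, and a dimensioned base only with
    an integer-literal exponent; transcendental functions require and
    return dimensionless; ``abs`` and ``random`` preserve their
    argument's dimension.
    """
    if isinstance(e, Lit):
        return DIMENSIONLESS
    if isinstance(e, Sym):
        try:
            return scope[e.name]
        except KeyError:
            raise DimensionInconsistency(f"unresolved symbol {e.name!r}", e) from None
    if isinstance(e, Un):
        d = infer_dimension(e.operand, scope)
        if e.op == "not" and not d.is_dimensionless:
            raise DimensionInconsistency("'not' requires a dimensionless operand", e)
        return d
    if isinstance(e, Call):
        d = infer_dimension(e.args[0], scope)
        if e.func in ("abs", "random"):
            return d
        if not d.is_dimensionless:
            raise DimensionInconsistency(
                f"function {e.func!r} requires a dimensionless argument", e
            )
        return DIMENSIONLESS
    assert isinstance(e, Bin)
    if e.op in ("+", "-"):
        dl = infer_dimension(e.left, scope)
        dr = infer_dimension(e.right, scope)
        if dl != dr:
            raise DimensionInconsistency(
                f"operands of {e.op!r} have dimensions "
                f"{dl.name!r} and {dr.name!r}", e
            )
        return dl
    if e.op in ("*", "/"):
        dl = infer_dimension(e.left, scope)
        dr = infer_dimension(e.right, scope)
        return dl * dr if e.op == "*" else dl / dr
    if e.op == "^":
        dl = infer_dimension(e.left, scope)
        dr = infer_dimension(e.right, scope)
        if not dr.is_dimensionless:
            raise DimensionInconsistency("exponent must be dimensionless", e)
        if dl.is_dimensionless:
            return DIMENSIONLESS
        if isinstance(e.right, Lit) and float(e.right.value).is_integer():
            return dl ** int(e.right.value)
        raise DimensionInconsistency(
            "a dimensioned base requires an integer literal exponent", e
        )
    if e.op in (">", "<", ">=", "<=", "==", "!="):
        dl = infer_dimension(e.left, scope)
        dr = infer_dimension(e.right, scope)
        if dl != dr and not (_is_zero_literal(e.left) or _is_zero_literal(e.right)):
            raise DimensionInconsistency(
                f"comparison of {dl.name!r} against {dr.name!r}", e
            )
        return DIMENSIONLESS
    # and / or
    dl = infer_dimension(e.left, scope)
    dr = infer_dimension(e.right, scope)
    if not (dl.is_dimensionless and dr.is_dimensionless):
        raise DimensionInconsistency(
            f"{e.op!r} requires dimensionless operands", e
        )
    return DIMENSIONLESS


class EvaluationError(ValueError):
    """Unbound symbol or numeric domain error during evaluation."""


def evaluate(e: Expr, scope: Mapping[str, float], rng=None) -> float:
    """Reference recursive evaluator (IEEE doubles; booleans as 1.0/0.0)."""
    if isinstance(e, Lit):
        return e.value
    if isinstance(e, Sym):
        try:
            return float(scope[e.name])
        except KeyError:
            raise EvaluationError(f"unbound symbol {e.name!r}") from None
    if isinstance(e, Un):
        v = evaluate(e.operand, scope, rng)
        return -v if e.op == "neg" else (0.0 if v != 0.0 else 1.0)
    if isinstance(e, Call):
        v = evaluate(e.args[0], scope, rng)
        if e.func == "random":
            if rng is None:
                raise EvaluationError("random() requires a seeded generator")
            return rng.random() * v
        fn = FUNCTIONS[e.func][1]
        try:
            return float(fn(v))
        except ValueError as exc:
            raise EvaluationError(f"{e.func}({v!r}): {exc}") from None
    assert isinstance(e, Bin)
    l = evaluate(e.left, scope, rng)
    r = evaluate(e.right, scope, rng)
    if e.op == "+":
        return l + r
    if e.op == "-":
        return l - r
    if e.op == "*":
        return l * r
    if e.op == "/":
        return l / r
    if e.op == "^":
        return l ** r
    if e.op == "and":
        return 1.0 if (l != 0.0 and r != 0.0) else 0.0
    if e.op == "or":
        return 1.0 if (l != 0.0 or r != 0.0) else 0.0
    cmp = {">": l > r, "<": l < r, ">=": l >= r, "<=": l <= r,
           "==": l == r, "!=": l != r}[e.op]
    return 1.0 if cmp else 0.0


def free_symbols(e: Expr) -> set[str]:
    if isinstance(e, Lit):
        return set()
    if isinstance(e, Sym):
        return {e.name}
    if isinstance(e, Un):
        return free_symbols(e.operand)
    if isinstance(e, Call):
        out: set[str] = set()
        for a in e.args:
            out |= free_symbols(a)
        return out
    return free_symbols(e.left) | free_symbols(e.right)


def _to_python(e: Expr) -> str:
    if isinstance(e, Lit):
        return repr(e.value)
    if isinstance(e, Sym):
        return f"s[{e.name!r}]"
    if isinstance(e, Un):
        inner = _to_python(e.operand)
        return f"(-({inner}))" if e.op == "neg" else f"(0.0 if ({inner}) != 0.0 else 1.0)"
    if isinstance(e, Call):
        a = _to_python(e.args[0])
        if e.func == "random":
            return f"(rng.random() * ({a}))"
        if e.func == "abs":
            return f"abs({a})"
        return f"math.{'log' if e.func in ('ln', 'log') else e.func}({a})"
    assert isinstance(e, Bin)
    l, r = _to_python(e.left), _to_python(e.right)
    if e.op == "^":
        return f"(({l}) ** ({r}))"
    if e.op in ("and", "or"):
        # bitwise on bools: both operands always evaluated, matching evaluate()
        bitop = "&" if e.op == "and" else "|"
        return f"(1.0 if ((({l}) != 0.0) {bitop} (({r}) != 0.0)) else 0.0)"
    if e.op in (">", "<", ">=", "<=", "==", "!="):
        return f"(1.0 if ({l}) {e.op} ({r}) else 0.0)"
    return f"(({l}) {e.op} ({r}))"


def compile_expr(e: Expr) -> Callable:
    """Compile to a fast ``f(scope, rng=None) -> float``.

    Semantically identical to :func:`evaluate`; used by the runtime's
    inner loop where tree-walking would dominate the step cost.
    """
    src = f"def _f(s, rng=None):\n    return float({_to_python(e)})\n"
    ns: dict = {"math": math, "abs": abs}
    exec(src, ns)
    return ns["_f"]
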