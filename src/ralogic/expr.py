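"""Boolean expression trees and the ``&``/``|``/``!`` rule dialect.

Expressions are immutable trees over variable names with AND/OR/NOT and the
constants 0/1.  Evaluation works both on scalar Python bools and on numpy
boolean arrays (the simulator compiles rules once and evaluates them
column-wise across runs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Mapping

__all__ = [
    "BoolExpr",
    "Var",
    "Not",
    "And",
    "Or",
    "Const",
    "TRUE",
    "FALSE",
    "ExprParseError",
    "parse_expr",
    "to_text",
    "variables",
    "evaluate",
    "substitute",
    "compile_expr",
    "equivalent",
]


class BoolExpr:
    """Base class; concrete nodes are Var, Not, And, Or, Const."""

    __slots__ = ()


@dataclass(frozen=True)
class Var(BoolExpr):
    name: str


@dataclass(frozen=True)
class Not(BoolExpr):
    operand: BoolExpr


@dataclass(frozen=True)
class And(BoolExpr):
    operands: tuple[BoolExpr, ...]


@dataclass(frozen=True)
class Or(BoolExpr):
    operands: tuple[BoolExpr, ...]


@dataclass(frozen=True)
class Const(BoolExpr):
    value: int  # 0 or 1


TRUE = Const(1)
FALSE = Const(0)


class ExprParseError(ValueError):
    """Raised on malformed rule text or undeclared symbols."""


def variables(expr: BoolExpr) -> frozenset[str]:
    """Set of variable names referenced by *expr*."""
    out: set[str] = set()
    stack = [expr]
    while stack:
        node = stack.pop()
        if isinstance(node, Var):
            out.add(node.name)
        elif isinstance(node, Not):
            stack.append(node.operand)
        elif isinstance(node, (And, Or)):
            stack.extend(node.operands)
    return frozenset(out)


def evaluate(expr: BoolExpr, env: Mapping[str, int]) -> int:
    """Evaluate *expr* to 0/1 under an assignment of 0/1 values."""
    if isinstance(expr, Var):
        return 1 if env[expr.name] else 0
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 1 - evaluate(expr.operand, env)
    if isinstance(expr, And):
        return int(all(evaluate(op, env) for op in expr.operands))
    if isinstance(expr, Or):
        return int(any(evaluate(op, env) for op in expr.operands))
    raise TypeError(f"not a BoolExpr: {expr!r}")


def substitute(expr: BoolExpr, mapping: Mapping[str, BoolExpr]) -> BoolExpr:
    """Replace variables by expressions (used by model reduction)."""
    if isinstance(expr, Var):
        return mapping.get(expr.name, expr)
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Not):
        return Not(substitute(expr.operand, mapping))
    if isinstance(expr, And):
        return And(tuple(substitute(op, mapping) for op in expr.operands))
    if isinstance(expr, Or):
        return Or(tuple(substitute(op, mapping) for op in expr.operands))
    raise TypeError(f"not a BoolExpr: {expr!r}")


def compile_expr(expr: BoolExpr, index: Mapping[str, int]) -> Callable:
    """Compile to ``f(state)`` where state is a 2-D bool array (rows x vars).

    Works equally on 1-D integer bit-columns (the fixed-point engine) because
    only ``& | ~`` and broadcasting are used.
    """
    src = _compile_src(expr, index)
    return eval(f"lambda s: ({src})", {})  # noqa: S307 - generated from our own AST


def _compile_src(expr: BoolExpr, index: Mapping[str, int]) -> str:
    if isinstance(expr, Var):
        return f"s[..., {index[expr.name]}]"
    if isinstance(expr, Const):
        return "(s[..., 0] | True)" if expr.value else "(s[..., 0] & False)"
    if isinstance(expr, Not):
        return f"~({_compile_src(expr.operand, index)})"
    if isinstance(expr, And):
        return "(" + " & ".join(_compile_src(op, index) for op in expr.operands) + ")"
    if isinstance(expr, Or):
        return "(" + " | ".join(_compile_src(op, index) for op in expr.operands) + ")"
    raise TypeError(f"not a BoolExpr: {expr!r}")


def to_text(expr: BoolExpr) -> str:
    """Serialize with ``&``, ``|``, ``!`` and minimal parentheses."""
    return _to_text(expr, 0)


# precedence: Or=1 < And=2 < Not=3
def _to_text(expr: BoolExpr, parent_prec: int) -> str:
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Not):
        return "!" + _to_text(expr.operand, 3)
    if isinstance(expr, And):
        text = " & ".join(_to_text(op, 2) for op in expr.operands)
        return f"({text})" if parent_prec > 2 or len(expr.operands) == 0 else text
    if isinstance(expr, Or):
        text = " | ".join(_to_text(op, 1) for op in expr.operands)
        return f"({text})" if parent_prec > 1 or len(expr.operands) == 0 else text
    raise TypeError(f"not a BoolExpr: {expr!r}")


def equivalent(a: BoolExpr, b: BoolExpr) -> bool:
    """Truth-table equality (enumeration; intended for small rule arities)."""
    names = sorted(variables(a) | variables(b))
    if len(names) > 20:
        raise ValueError("too many variables for truth-table comparison")
    for bits in range(1 << len(names)):
        env = {n: (bits >> i) & 1 for i, n in enumerate(names)}
        if evaluate(a, env) != evaluate(b, env):
            return False
    return True


# ----------------------------------------------------------------------------
# Parser: expr := term ('|' term)*; term := factor ('&' factor)*;
#         factor := '!' factor | '(' expr ')' | NAME | '0' | '1'
# ----------------------------------------------------------------------------

_SYMBOL_CHARS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_")


def _tokenize(text: str) -> Iterator[str]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "&|!()":
            yield ch
            i += 1
            continue
        if ch in _SYMBOL_CHARS:
            j = i
            while j < n and text[j] in _SYMBOL_CHARS:
                j += 1
            yield text[i:j]
            i = j
            continue
        raise ExprParseError(f"unexpected character {ch!r} in expression {text!r}")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExprParseError(f"unexpected end of expression in {self.text!r}")
        self.pos += 1
        return tok

    def parse(self) -> BoolExpr:
        expr = self.expr()
        if self.peek() is not None:
            raise ExprParseError(
                f"trailing tokens {self.tokens[self.pos:]} in expression {self.text!r}"
            )
        return expr

    def expr(self) -> BoolExpr:
        terms = [self.term()]
        while self.peek() == "|":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term(self) -> BoolExpr:
        factors = [self.factor()]
        while self.peek() == "&":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor(self) -> BoolExpr:
        tok = self.next()
        if tok == "!":
            return Not(self.factor())
        if tok == "(":
            inner = self.expr()
            if self.next() != ")":
                raise ExprParseError(f"unbalanced parentheses in {self.text!r}")
            return inner
        if tok in "&|)":
            raise ExprParseError(f"unexpected token {tok!r} in expression {self.text!r}")
        if tok == "0":
            return FALSE
        if tok == "1":
            return TRUE
        return Var(tok)


def parse_expr(text: str) -> BoolExpr:
    """Parse rule text such as ``A & !(B | C)`` into an expression tree."""
    if not text.strip():
        raise ExprParseError("empty expression")
    return _Parser(text).parse()
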