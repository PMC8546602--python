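"""Arithmetic expression engine for parametric path templates.

Coordinates inside a parametric glyph file are not bare numbers but small
arithmetic formulas over named parameters, e.g. ``width - arrowhead_width``
or ``-height/2``.  This module parses such formulas into an abstract syntax
tree and evaluates them against a binding of parameter names to values.

Grammar (infix, left-associative, conventional precedence, unary minus
binding tighter than ``*``/``/``)::

    expr   := term   (('+' | '-') term)*
    term   := factor (('*' | '/') factor)*
    factor := '-' factor | atom
    atom   := NUMBER | NAME | NAME '(' expr (',' expr)* ')' | '(' expr ')'

The function table is fixed: ``sin``, ``cos``, ``tan``, ``sqrt``, ``abs``
(unary) and ``min``, ``max`` (binary).  Trigonometric functions take
radians.  Numeric literals are decimal with optional fraction and exponent.
Whitespace is insignificant.  Unknown parameter names are detected at
evaluation time, not at parse time, so a glyph library can be parsed before
any bindings exist.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .errors import EvaluationError, ExpressionError

__all__ = [
    "Expression",
    "Literal",
    "Param",
    "Neg",
    "BinOp",
    "Call",
    "FUNCTIONS",
    "parse_expression",
    "evaluate",
    "list_parameters",
]


@dataclass(frozen=True)
class Literal:
    value: float


@dataclass(frozen=True)
class Param:
    name: str


@dataclass(frozen=True)
class Neg:
    operand: "Expression"


@dataclass(frozen=True)
class BinOp:
    op: str  # one of + - * /
    left: "Expression"
    right: "Expression"


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple["Expression", ...]


Expression = Literal | Param | Neg | BinOp | Call

#: function name -> (arity, implementation)
FUNCTIONS: dict[str, tuple[int, object]] = {
    "sin": (1, math.sin),
    "cos": (1, math.cos),
    "tan": (1, math.tan),
    "sqrt": (1, math.sqrt),
    "abs": (1, abs),
    "min": (2, min),
    "max": (2, max),
}

_TOKEN_RE = re.compile(
    r"""
    (?P<number>(?:\d+(?:\.\d*)?|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op>[-+*/(),])
  | (?P<ws>\s+)
  | (?P<bad>.)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        if kind == "ws":
            continue
        if kind == "bad":
            raise ExpressionError(f"unexpected character {m.group()!r}", m.start())
        tokens.append((kind, m.group(), m.start()))
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.pos]

    def next(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect_op(self, op: str) -> None:
        kind, value, at = self.peek()
        if kind != "op" or value != op:
            shown = value or "end of input"
            raise ExpressionError(f"expected {op!r}, found {shown!r}", at)
        self.next()

    def parse(self) -> Expression:
        node = self.expr()
        kind, value, at = self.peek()
        if kind != "end":
            raise ExpressionError(f"unexpected token {value!r}", at)
        return node

    def expr(self) -> Expression:
        node = self.term()
        while True:
            kind, value, _ = self.peek()
            if kind == "op" and value in "+-":
                self.next()
                node = BinOp(value, node, self.term())
            else:
                return node

    def term(self) -> Expression:
        node = self.factor()
        while True:
            kind, value, _ = self.peek()
            if kind == "op" and value in "*/":
                self.next()
                node = BinOp(value, node, self.factor())
            else:
                return node

    def factor(self) -> Expression:
        kind, value, _ = self.peek()
        if kind == "op" and value == "-":
            self.next()
            return Neg(self.factor())
        return self.atom()

    def atom(self) -> Expression:
        kind, value, at = self.next()
        if kind == "number":
            return Literal(float(value))
        if kind == "name":
            nkind, nvalue, _ = self.peek()
            if nkind == "op" and nvalue == "(":
                return self.call(value, at)
            return Param(value)
        if kind == "op" and value == "(":
            node = self.expr()
            self.expect_op(")")
            return node
        shown = value or "end of input"
        raise ExpressionError(f"unexpected token {shown!r}", at)

    def call(self, name: str, at: int) -> Expression:
        if name not in FUNCTIONS:
            raise ExpressionError(f"unknown function {name!r}", at)
        self.expect_op("(")
        args = [self.expr()]
        while True:
            kind, value, _ = self.peek()
            if kind == "op" and value == ",":
                self.next()
                args.append(self.expr())
            else:
                break
        self.expect_op(")")
        arity = FUNCTIONS[name][0]
        if len(args) != arity:
            raise ExpressionError(
                f"function {name!r} takes {arity} argument(s), got {len(args)}", at
            )
        return Call(name, tuple(args))


def parse_expression(text: str) -> Expression:
    """Parse an expression string into an AST.

    Raises :class:`~sbolv.errors.ExpressionError` naming the offending token
    and position on malformed input, unknown functions or wrong arity.
    """
    if not text or not text.strip():
        raise ExpressionError("empty expression", 0)
    return _Parser(text).parse()


def evaluate(expr: Expression | str, binding: dict[str, float]) -> float:
    """Evaluate an expression (or expression string) against *binding*.

    Trigonometric functions use radians.  Division by zero and unbound
    parameters raise :class:`~sbolv.errors.EvaluationError`.
    """
    if isinstance(expr, str):
        expr = parse_expression(expr)
    return _eval(expr, binding)


def _eval(node: Expression, binding: dict[str, float]) -> float:
    if isinstance(node, Literal):
        return node.value
    if isinstance(node, Param):
        try:
            return float(binding[node.name])
        except KeyError:
            raise EvaluationError(f"unbound parameter {node.name!r}") from None
    if isinstance(node, Neg):
        return -_eval(node.operand, binding)
    if isinstance(node, BinOp):
        left = _eval(node.left, binding)
        right = _eval(node.right, binding)
        if node.op == "+":
            return left + right
        if node.op == "-":
            return left - right
        if node.op == "*":
            return left * right
        if right == 0.0:
            raise EvaluationError(f"division by zero in {node.op!r} expression")
        return left / right
    if isinstance(node, Call):
        args = [_eval(a, binding) for a in node.args]
        try:
            return float(FUNCTIONS[node.func][1](*args))
        except ValueError as exc:  # e.g. sqrt of a negative number
            raise EvaluationError(f"{node.func}: {exc}") from None
    raise TypeError(f"not an expression node: {node!r}")


def list_parameters(expr: Expression | str) -> set[str]:
    """Return the set of parameter names referenced by *expr*."""
    if isinstance(expr, str):
        expr = parse_expression(expr)
    names: set[str] = set()
    _collect(expr, names)
    return names


def _collect(node: Expression, names: set[str]) -> None:
    if isinstance(node, Param):
        names.add(node.name)
    elif isinstance(node, Neg):
        _collect(node.operand, names)
    elif isinstance(node, BinOp):
        _collect(node.left, names)
        _collect(node.right, names)
    elif isinstance(node, Call):
        for a in node.args:
            _collect(a, names)
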