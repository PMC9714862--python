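"""Logical premises: parsing and three-valued evaluation.

A character may carry a *logical premise* — a boolean expression over
established facts that must hold before the character is shown to the user
(e.g. wing characters only once wings have been affirmed).  Premises are
written in JavaScript-style infix notation over state ids, numerical
character ids, numbers and boolean literals::

    state:has_wings && character:weight > 5

Because a session rarely knows the truth of every fact, evaluation is
three-valued (Kleene logic): a fact that is neither affirmed nor refuted is
UNKNOWN, and UNKNOWN propagates through operators unless the known operands
already force the result (``UNKNOWN && FALSE`` is ``FALSE``,
``UNKNOWN || TRUE`` is ``TRUE``).

Grammar (EBNF)::

    expr        = or_expr ;
    or_expr     = and_expr , { "||" , and_expr } ;
    and_expr    = cmp_expr , { "&&" , cmp_expr } ;
    cmp_expr    = unary , [ ( "==" | "!=" | "<" | "<=" | ">" | ">=" ) , unary ] ;
    unary       = { "!" | "-" } , atom ;
    atom        = "true" | "false" | number | identifier | "(" , expr , ")" ;
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional, Union

from .format import Key, ClavisError

__all__ = [
    "TriState",
    "FactContext",
    "PremiseAst",
    "Lit",
    "Num",
    "Ident",
    "Unary",
    "Binary",
    "PremiseSyntaxError",
    "PremiseTypeError",
    "parse_premise",
    "unparse",
    "evaluate_premise",
    "premise_identifiers",
]


class TriState(enum.Enum):
    """Kleene truth value."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("TriState is three-valued; compare explicitly")


T, F, U = TriState.TRUE, TriState.FALSE, TriState.UNKNOWN


def kleene_not(a: TriState) -> TriState:
    return {T: F, F: T, U: U}[a]


def kleene_and(a: TriState, b: TriState) -> TriState:
    if a is F or b is F:
        return F
    if a is T and b is T:
        return T
    return U


def kleene_or(a: TriState, b: TriState) -> TriState:
    if a is T or b is T:
        return T
    if a is F and b is F:
        return F
    return U


# -- AST --------------------------------------------------------------------


@dataclass(frozen=True)
class Lit:
    value: bool


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Ident:
    name: str


@dataclass(frozen=True)
class Unary:
    op: str  # "!" | "-"
    operand: "PremiseAst"


@dataclass(frozen=True)
class Binary:
    op: str  # "&&" "||" "==" "!=" "<" "<=" ">" ">="
    left: "PremiseAst"
    right: "PremiseAst"


PremiseAst = Union[Lit, Num, Ident, Unary, Binary]


class PremiseSyntaxError(ClavisError):
    """Syntax error in a premise string, annotated with its position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class PremiseTypeError(ClavisError):
    """Operands of incompatible kinds (e.g. a boolean compared with <)."""


class UnknownIdentifierError(ClavisError):
    """The premise references an id that does not exist in the key."""

    def __init__(self, name: str):
        super().__init__(f"unknown identifier '{name}' in premise")
        self.name = name


_TOKEN = re.compile(
    r"\s*(?:(?P<op>&&|\|\||==|!=|<=|>=|<|>|!|-|\(|\))"
    r"|(?P<num>\d+(?:\.\d+)?)"
    r"|(?P<ident>[A-Za-z_][\w:.\-]*))"
)


def _tokenize(src: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(src):
        m = _TOKEN.match(src, pos)
        if not m or m.end() == pos:
            if src[pos:].strip():
                raise PremiseSyntaxError(f"unexpected character {src[pos]!r}", pos)
            break
        if m.group("op"):
            tokens.append(("op", m.group("op"), m.start("op")))
        elif m.group("num"):
            tokens.append(("num", m.group("num"), m.start("num")))
        else:
            tokens.append(("ident", m.group("ident"), m.start("ident")))
        pos = m.end()
    return tokens


_CMP_OPS = ("==", "!=", "<", "<=", ">", ">=")


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], src_len: int):
        self.tokens = tokens
        self.i = 0
        self.src_len = src_len

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise PremiseSyntaxError("unexpected end of premise", self.src_len)
        self.i += 1
        return tok

    def expect_op(self, op: str) -> None:
        tok = self.next()
        if tok[0] != "op" or tok[1] != op:
            raise PremiseSyntaxError(f"expected '{op}', found {tok[1]!r}", tok[2])

    def parse(self) -> PremiseAst:
        node = self.or_expr()
        tok = self.peek()
        if tok is not None:
            raise PremiseSyntaxError(f"unexpected trailing token {tok[1]!r}", tok[2])
        return node

    def or_expr(self) -> PremiseAst:
        node = self.and_expr()
        while (tok := self.peek()) and tok[:2] == ("op", "||"):
            self.next()
            node = Binary("||", node, self.and_expr())
        return node

    def and_expr(self) -> PremiseAst:
        node = self.cmp_expr()
        while (tok := self.peek()) and tok[:2] == ("op", "&&"):
            self.next()
            node = Binary("&&", node, self.cmp_expr())
        return node

    def cmp_expr(self) -> PremiseAst:
        node = self.unary()
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] in _CMP_OPS:
            self.next()
            node = Binary(tok[1], node, self.unary())
        return node

    def unary(self) -> PremiseAst:
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] in ("!", "-"):
            self.next()
            return Unary(tok[1], self.unary())
        return self.atom()

    def atom(self) -> PremiseAst:
        tok = self.next()
        kind, text, pos = tok
        if kind == "num":
            return Num(float(text))
        if kind == "ident":
            if text == "true":
                return Lit(True)
            if text == "false":
                return Lit(False)
            return Ident(text)
        if kind == "op" and text == "(":
            node = self.or_expr()
            self.expect_op(")")
            return node
        raise PremiseSyntaxError(f"unexpected token {text!r}", pos)


def parse_premise(src: str, key: Optional[Key] = None) -> PremiseAst:
    """Parse a premise string into an expression tree.

    Precedence (high to low): unary ``!``/``-``, comparisons, ``&&``,
    ``||``; binary operators are left-associative.  When a ``key`` is
    given, every identifier must match one of its state ids or numerical
    character ids verbatim; an unmatched identifier raises
    :class:`UnknownIdentifierError`.
    """
    if not src or not src.strip():
        raise PremiseSyntaxError("empty premise", 0)
    ast = _Parser(_tokenize(src), len(src)).parse()
    if key is not None:
        known = set(key.state_owner())
        known.update(c.id for c in key.characters if c.is_numerical)
        for name in premise_identifiers(ast):
            if name not in known:
                raise UnknownIdentifierError(name)
    return ast


def premise_identifiers(ast: PremiseAst) -> list[str]:
    """All identifiers referenced by the tree, in first-appearance order."""
    out: list[str] = []

    def walk(node: PremiseAst) -> None:
        if isinstance(node, Ident):
            if node.name not in out:
                out.append(node.name)
        elif isinstance(node, Unary):
            walk(node.operand)
        elif isinstance(node, Binary):
            walk(node.left)
            walk(node.right)

    walk(ast)
    return out


def unparse(ast: PremiseAst) -> str:
    """Render a tree back to premise notation (fully parenthesized)."""
    if isinstance(ast, Lit):
        return "true" if ast.value else "false"
    if isinstance(ast, Num):
        v = ast.value
        return str(int(v)) if v == int(v) else repr(v)
    if isinstance(ast, Ident):
        return ast.name
    if isinstance(ast, Unary):
        return f"{ast.op}({unparse(ast.operand)})"
    return f"({unparse(ast.left)} {ast.op} {unparse(ast.right)})"


# -- Evaluation -------------------------------------------------------------

AFFIRMED = "affirmed"
REJECTED = "rejected"
IMPOSSIBLE = "impossible"
UNKNOWN = "unknown"


@dataclass
class FactContext:
    """Facts established during a session.

    ``states`` maps state ids to one of ``affirmed`` / ``rejected`` /
    ``impossible`` / ``unknown`` ("impossible" marks states every surviving
    taxon is known not to have, including exclusivity-implied ones);
    ``numbers`` maps numerical character ids to the user's answer, or None
    while unanswered.
    """

    states: dict[str, str]
    numbers: dict[str, Optional[float]]

    def state_truth(self, state_id: str) -> TriState:
        status = self.states.get(state_id, UNKNOWN)
        if status == AFFIRMED:
            return T
        if status in (REJECTED, IMPOSSIBLE):
            return F
        return U


# evaluation results are TriState (boolean), float (number) or None
# (a number whose value is not yet known)
_EvalValue = Union[TriState, float, None]


def _eval(node: PremiseAst, facts: FactContext) -> _EvalValue:
    if isinstance(node, Lit):
        return T if node.value else F
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Ident):
        if node.name in facts.numbers:
            return facts.numbers[node.name]  # float or None (unanswered)
        return facts.state_truth(node.name)
    if isinstance(node, Unary):
        v = _eval(node.operand, facts)
        if node.op == "!":
            if not isinstance(v, TriState):
                raise PremiseTypeError("'!' applied to a numeric value")
            return kleene_not(v)
        # numeric negation
        if isinstance(v, TriState):
            raise PremiseTypeError("unary '-' applied to a boolean value")
        return None if v is None else -v
    assert isinstance(node, Binary)
    if node.op in ("&&", "||"):
        left = _eval(node.left, facts)
        right = _eval(node.right, facts)
        if not isinstance(left, TriState) or not isinstance(right, TriState):
            raise PremiseTypeError(f"'{node.op}' requires boolean operands")
        return kleene_and(left, right) if node.op == "&&" else kleene_or(left, right)
    left = _eval(node.left, facts)
    right = _eval(node.right, facts)
    numeric_l = not isinstance(left, TriState)
    numeric_r = not isinstance(right, TriState)
    if node.op in ("<", "<=", ">", ">="):
        if not (numeric_l and numeric_r):
            raise PremiseTypeError(f"'{node.op}' requires numeric operands")
        if left is None or right is None:
            return U
        ops = {
            "<": left < right,
            "<=": left <= right,
            ">": left > right,
            ">=": left >= right,
        }
        return T if ops[node.op] else F
    # == / != accept two numbers or two booleans
    if numeric_l != numeric_r:
        raise PremiseTypeError(f"'{node.op}' operands of mixed kind")
    if numeric_l:
        if left is None or right is None:
            return U
        eq = T if left == right else F
    else:
        if left is U or right is U:
            return U
        eq = T if left is right else F
    return eq if node.op == "==" else kleene_not(eq)


def evaluate_premise(ast: PremiseAst, facts: FactContext) -> TriState:
    """Evaluate a premise tree under the facts established so far.

    A state identifier is TRUE when affirmed, FALSE when rejected or
    impossible, UNKNOWN otherwise; a numerical identifier whose value is
    unanswered makes any comparison on it UNKNOWN.  Connectives follow the
    Kleene tables.  Raises :class:`PremiseTypeError` on kind mismatches
    (e.g. ordering two booleans).
    """
    v = _eval(ast, facts)
    if not isinstance(v, TriState):
        raise PremiseTypeError("premise evaluates to a number, not a truth value")
    return v
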