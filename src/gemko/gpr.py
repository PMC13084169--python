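"""Boolean gene-protein-reaction (GPR) rules.

A reaction's GPR is a boolean expression over gene identifiers in which
``and`` joins the subunits of an enzyme complex (all genes required) and
``or`` joins isozymes (any one gene suffices).  Under a gene deletion the
deleted genes evaluate to False; a reaction whose rule evaluates to False
has lost all catalysing enzymes and is disabled.

Grammar (case-insensitive keywords, ``and`` binds tighter than ``or``)::

    expr   := term ("or" term)*
    term   := factor ("and" factor)*
    factor := "(" expr ")" | GENE_ID

A gene identifier is any run of characters other than whitespace and
parentheses that is not one of the keywords.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "GprParseError",
    "GprRule",
    "parse_gpr",
    "rule_active",
    "EMPTY_RULE",
]


class GprParseError(ValueError):
    """Raised when a rule string cannot be parsed; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# Expression tree


@dataclass(frozen=True)
class _Node:
    def evaluate(self, deleted: frozenset[str]) -> bool:  # pragma: no cover
        raise NotImplementedError

    def genes(self) -> frozenset[str]:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class Gene(_Node):
    name: str

    def evaluate(self, deleted: frozenset[str]) -> bool:
        return self.name not in deleted

    def genes(self) -> frozenset[str]:
        return frozenset((self.name,))

    def to_string(self) -> str:
        return self.name


@dataclass(frozen=True)
class And(_Node):
    children: tuple[_Node, ...]

    def evaluate(self, deleted: frozenset[str]) -> bool:
        return all(c.evaluate(deleted) for c in self.children)

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self) -> str:
        parts = [
            f"({c.to_string()})" if isinstance(c, Or) else c.to_string()
            for c in self.children
        ]
        return " and ".join(parts)


@dataclass(frozen=True)
class Or(_Node):
    children: tuple[_Node, ...]

    def evaluate(self, deleted: frozenset[str]) -> bool:
        return any(c.evaluate(deleted) for c in self.children)

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self) -> str:
        return " or ".join(c.to_string() for c in self.children)


@dataclass(frozen=True)
class GprRule:
    """A parsed GPR rule; ``expression is None`` means "no gene constraint"."""

    expression: _Node | None = None
    source_text: str = ""

    @property
    def is_empty(self) -> bool:
        return self.expression is None

    def genes(self) -> frozenset[str]:
        """All gene identifiers appearing in the rule."""
        if self.expression is None:
            return frozenset()
        return self.expression.genes()

    def to_string(self) -> str:
        """Canonical serialization, logically equivalent to the source."""
        if self.expression is None:
            return ""
        return self.expression.to_string()

    def __bool__(self) -> bool:
        return not self.is_empty


EMPTY_RULE = GprRule()


# ---------------------------------------------------------------------------
# Parser

_KEYWORDS = {"and", "or"}


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    """Yield (kind, value, position); kind in {'(', ')', 'and', 'or', 'gene'}."""
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            yield ch, ch, i
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in _KEYWORDS:
            yield low, word, i
        else:
            yield "gene", word, i
        i = j


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def _peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> _Node:
        node = self._expr()
        tok = self._peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def _expr(self) -> _Node:
        terms = [self._term()]
        while (tok := self._peek()) is not None and tok[0] == "or":
            self._advance()
            terms.append(self._term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def _term(self) -> _Node:
        factors = [self._factor()]
        while (tok := self._peek()) is not None and tok[0] == "and":
            self._advance()
            factors.append(self._factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def _factor(self) -> _Node:
        tok = self._peek()
        if tok is None:
            raise GprParseError("dangling operator or empty expression", len(self.text))
        kind, value, pos = tok
        if kind == "(":
            self._advance()
            node = self._expr()
            closing = self._peek()
            if closing is None or closing[0] != ")":
                raise GprParseError("unbalanced parentheses", pos)
            self._advance()
            return node
        if kind == "gene":
            self._advance()
            return Gene(value)
        raise GprParseError(f"unexpected token {value!r}", pos)


def parse_gpr(text: str) -> GprRule:
    """Parse a GPR rule string into an expression tree.

    An empty or whitespace-only string yields the empty rule, meaning the
    reaction is not gene-constrained and survives every deletion.

    Raises
    ------
    GprParseError
        On unbalanced parentheses, dangling operators or stray tokens;
        the error message includes the character position.
    """
    if not text or not text.strip():
        return EMPTY_RULE
    return GprRule(expression=_Parser(text).parse(), source_text=text)


def rule_active(rule: GprRule, deleted: set[str] | frozenset[str]) -> bool:
    """Evaluate a rule under a set of deleted genes.

    Leaves evaluate to False iff their gene is in ``deleted``; AND/OR are
    evaluated bottom-up.  The empty rule is always active (no enzyme
    requirement is encoded, so no deletion can disable the reaction).
    """
    if rule.expression is None:
        return True
    return rule.expression.evaluate(frozenset(deleted))
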