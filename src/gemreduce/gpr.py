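"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers combined with AND/OR
(case-insensitive) and parentheses.  A reaction with an empty rule is treated
as always catalysable: missing gene data must not create spurious
essentiality.  Rules are parsed once into an expression tree that supports
evaluation under a set of deleted genes, gene extraction, and re-rendering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Tuple

from .errors import GPRParseError

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

# Node encoding: ("gene", id) | ("and", (children,)) | ("or", (children,))
Node = Tuple[str, object]


def _tokenize(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


class _Parser:
    """Recursive descent over  expr := term (OR term)* ; term := atom (AND atom)*."""

    def __init__(self, tokens: list[str], rule: str):
        self.tokens = tokens
        self.pos = 0
        self.rule = rule

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule: {self.rule!r}")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        if self.peek() is not None:
            raise GPRParseError(f"trailing token {self.peek()!r} in rule {self.rule!r}")
        return node

    def expr(self) -> Node:
        terms = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else ("or", tuple(terms))

    def term(self) -> Node:
        atoms = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            atoms.append(self.atom())
        return atoms[0] if len(atoms) == 1 else ("and", tuple(atoms))

    def atom(self) -> Node:
        tok = self.next()
        if tok == "(":
            node = self.expr()
            if self.next() != ")":
                raise GPRParseError(f"unbalanced parentheses in rule {self.rule!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in rule {self.rule!r}")
        return ("gene", tok)


def _eval(node: Node, deleted: frozenset) -> bool:
    kind, payload = node
    if kind == "gene":
        return payload not in deleted
    if kind == "and":
        return all(_eval(c, deleted) for c in payload)
    return any(_eval(c, deleted) for c in payload)


def _genes(node: Node) -> frozenset:
    kind, payload = node
    if kind == "gene":
        return frozenset((payload,))
    out: set = set()
    for c in payload:
        out |= _genes(c)
    return frozenset(out)


def _render(node: Node, parent: str | None = None) -> str:
    kind, payload = node
    if kind == "gene":
        return payload
    joiner = " and " if kind == "and" else " or "
    body = joiner.join(_render(c, kind) for c in payload)
    # parenthesize OR under AND to keep precedence explicit
    if parent is not None and parent != kind:
        return f"({body})"
    return body


@dataclass(frozen=True)
class GPR:
    """Parsed gene-protein-reaction rule; empty tree means always-on."""

    tree: Node | None

    @classmethod
    def from_string(cls, rule: str | None) -> "GPR":
        if rule is None or not rule.strip():
            return cls(None)
        return cls(_Parser(_tokenize(rule), rule).parse())

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        """True iff the reaction remains catalysable after the deletions."""
        if self.tree is None:
            return True
        return _eval(self.tree, frozenset(deleted_genes))

    @property
    def genes(self) -> FrozenSet[str]:
        return frozenset() if self.tree is None else _genes(self.tree)

    def to_string(self) -> str:
        return "" if self.tree is None else _render(self.tree)

    @property
    def is_empty(self) -> bool:
        return self.tree is None


def conjoin(rules: Iterable[GPR]) -> GPR:
    """AND-combine rules (used for lumped reactions); empty rules drop out."""
    parts = [r.tree for r in rules if r.tree is not None]
    if not parts:
        return GPR(None)
    if len(parts) == 1:
        return GPR(parts[0])
    return GPR(("and", tuple(parts)))


def disjoin(rules: Iterable[GPR]) -> GPR:
    """OR-combine rules (used when lumps with identical stoichiometry merge).

    An empty member rule means always-on, which dominates the disjunction.
    """
    parts = []
    for r in rules:
        if r.tree is None:
            return GPR(None)
        parts.append(r.tree)
    if not parts:
        return GPR(None)
    if len(parts) == 1:
        return GPR(parts[0])
    return GPR(("or", tuple(parts)))
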