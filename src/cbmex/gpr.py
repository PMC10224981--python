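"""Boolean gene-protein-reaction (GPR) rules.

A GPR rule links a reaction to the genes whose products catalyse it, as a
boolean expression over gene identifiers with AND (complex subunits) and OR
(isoenzymes). Rules are parsed from the conventional string form used in
COBRA-style model files, e.g. ``"g1 and (g2 or g3)"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class GprParseError(ValueError):
    """Raised when a GPR rule string is malformed."""


@dataclass(frozen=True)
class GprRule:
    """Node of a GPR expression tree.

    ``op`` is ``"gene"`` for a leaf (with ``gene`` set), or ``"and"`` /
    ``"or"`` for an internal node with two or more ``children``.
    """

    op: str
    gene: str | None = None
    children: tuple["GprRule", ...] = field(default=())

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene or self.children:
                raise GprParseError("leaf node must carry a gene id and no children")
        elif self.op in ("and", "or"):
            if len(self.children) < 2 or self.gene is not None:
                raise GprParseError(f"'{self.op}' node needs >= 2 children and no gene id")
        else:
            raise GprParseError(f"unknown GPR operator {self.op!r}")

    @classmethod
    def leaf(cls, gene: str) -> "GprRule":
        return cls("gene", gene=gene)

    @classmethod
    def all_of(cls, *children: "GprRule") -> "GprRule":
        return children[0] if len(children) == 1 else cls("and", children=tuple(children))

    @classmethod
    def any_of(cls, *children: "GprRule") -> "GprRule":
        return children[0] if len(children) == 1 else cls("or", children=tuple(children))

    def genes(self) -> frozenset[str]:
        """Set of gene ids appearing anywhere in the rule."""
        if self.op == "gene":
            return frozenset([self.gene])  # type: ignore[list-item]
        out: frozenset[str] = frozenset()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, active_genes: set[str] | frozenset[str]) -> bool:
        """Evaluate the boolean rule given the set of active genes."""
        if self.op == "gene":
            return self.gene in active_genes
        if self.op == "and":
            return all(c.evaluate(active_genes) for c in self.children)
        return any(c.evaluate(active_genes) for c in self.children)

    def to_string(self) -> str:
        """Serialize back to the conventional ``and``/``or`` string form."""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            text = child.to_string()
            # parenthesize an OR under an AND; keep everything else flat
            if self.op == "and" and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)

    def equivalent(self, other: "GprRule") -> bool:
        """Truth-table equality over the union of both gene sets."""
        genes = sorted(self.genes() | other.genes())
        for mask in range(2 ** len(genes)):
            active = {g for i, g in enumerate(genes) if mask >> i & 1}
            if self.evaluate(active) != other.evaluate(active):
                return False
        return True


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN.findall(text)


class _Parser:
    """Recursive-descent parser; ``and`` binds tighter than ``or``."""

    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR rule: {self.source!r}")
        self.pos += 1
        return tok

    def parse(self) -> GprRule:
        rule = self.or_expr()
        if self.peek() is not None:
            raise GprParseError(f"trailing tokens in GPR rule: {self.source!r}")
        return rule

    def or_expr(self) -> GprRule:
        terms = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.and_expr())
        return GprRule.any_of(*terms)

    def and_expr(self) -> GprRule:
        factors = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.atom())
        return GprRule.all_of(*factors)

    def atom(self) -> GprRule:
        tok = self.next()
        if tok == "(":
            inner = self.or_expr()
            if self.peek() != ")":
                raise GprParseError(f"unbalanced parentheses in GPR rule: {self.source!r}")
            self.next()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"empty operand near {tok!r} in GPR rule: {self.source!r}")
        return GprRule.leaf(tok)


def parse_gpr(rule_text: str) -> GprRule | None:
    """Parse a GPR rule string into an expression tree.

    Returns ``None`` for an empty/whitespace-only rule (reaction with no
    gene association). ``and`` binds tighter than ``or``; explicit
    parentheses are honored.
    """
    if rule_text is None or not rule_text.strip():
        return None
    return _Parser(_tokenize(rule_text), rule_text).parse()
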