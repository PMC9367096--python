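"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule states which gene products a reaction needs: ``and`` means a complex
(all subunits required), ``or`` means isozymes (any one suffices).  Evaluating a
rule under a set of knocked-out genes decides whether the reaction can still
carry flux.  An absent (empty) rule always evaluates true.

The grammar is the conventional COBRA one: gene tokens, parentheses and the
case-insensitive keywords ``and`` / ``or``, with ``and`` binding tighter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GprExpression",
    "GprParseError",
    "parse_gpr",
    "format_gpr",
]

_KEYWORDS = {"and", "or"}


class GprParseError(ValueError):
    """Raised for malformed GPR strings; ``offset`` points at the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class GprExpression:
    """Node of a boolean AND/OR tree over gene identifiers.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"true"`` (the empty
    rule).  Gene nodes carry ``gene``; operator nodes carry ``children``.
    """

    op: str
    gene: str | None = None
    children: tuple["GprExpression", ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.op not in {"gene", "and", "or", "true"}:
            raise ValueError(f"unknown GPR node type {self.op!r}")
        if self.op == "gene" and not self.gene:
            raise ValueError("gene node requires a gene id")
        if self.op in {"and", "or"} and len(self.children) < 1:
            raise ValueError(f"{self.op} node requires children")

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, knocked: Iterable[str] = ()) -> bool:
        """True iff the rule is satisfied with ``knocked`` genes absent."""
        knocked = set(knocked)
        return self._eval(knocked)

    def _eval(self, knocked: set[str]) -> bool:
        if self.op == "true":
            return True
        if self.op == "gene":
            return self.gene not in knocked
        if self.op == "and":
            return all(c._eval(knocked) for c in self.children)
        return any(c._eval(knocked) for c in self.children)

    # -- introspection ------------------------------------------------------

    @property
    def genes(self) -> frozenset[str]:
        if self.op == "true":
            return frozenset()
        if self.op == "gene":
            return frozenset({self.gene})
        return frozenset().union(*(c.genes for c in self.children))

    @property
    def is_empty(self) -> bool:
        return self.op == "true"

    def minimal_cut_sets(
        self, candidates: Iterable[str] | None = None, max_genes: int = 16
    ) -> list[frozenset[str]]:
        """Minimal gene sets within ``candidates`` whose joint knockout kills the rule.

        Non-candidate genes are assumed present.  The rule is monotone, so
        minimal cut sets are found by ascending-cardinality enumeration over
        the rule's candidate genes (guarded to ``max_genes``).
        """
        pool = sorted(self.genes if candidates is None else self.genes & set(candidates))
        if len(pool) > max_genes:
            raise ValueError(f"GPR rule has {len(pool)} candidate genes (> {max_genes})")
        cuts: list[frozenset[str]] = []
        for k in range(1, len(pool) + 1):
            for combo in itertools.combinations(pool, k):
                s = frozenset(combo)
                if any(c <= s for c in cuts):
                    continue
                if not self.evaluate(s):
                    cuts.append(s)
        return cuts

    def prime_implicants(
        self, candidates: Iterable[str] | None = None, max_genes: int = 16
    ) -> list[frozenset[str]]:
        """Minimal candidate-gene sets whose presence keeps the rule satisfied.

        Complements :meth:`minimal_cut_sets`: the rule holds iff at least one
        prime implicant is fully present.  Returns ``[frozenset()]`` when the
        rule survives even with every candidate knocked.
        """
        pool = sorted(self.genes if candidates is None else self.genes & set(candidates))
        if len(pool) > max_genes:
            raise ValueError(f"GPR rule has {len(pool)} candidate genes (> {max_genes})")
        implicants: list[frozenset[str]] = []
        for k in range(0, len(pool) + 1):
            for combo in itertools.combinations(pool, k):
                present = frozenset(combo)
                if any(p <= present for p in implicants):
                    continue
                if self.evaluate(set(pool) - present):
                    implicants.append(present)
        return implicants

    # -- formatting ---------------------------------------------------------

    def __str__(self) -> str:
        return format_gpr(self)

    def _format(self, parent: str | None) -> str:
        if self.op == "true":
            return ""
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        body = sep.join(c._format(self.op) for c in self.children)
        # parenthesise every nested operator so tree shape survives re-parsing
        if parent in {"and", "or"}:
            return f"({body})"
        return body


GPR_TRUE = GprExpression(op="true")


def format_gpr(expr: GprExpression | None) -> str:
    """Canonical string form; the empty rule formats as ``""``."""
    if expr is None:
        return ""
    return expr._format(None)


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            yield ("paren", ch, i)
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        if word.lower() in _KEYWORDS:
            yield ("op", word.lower(), i)
        else:
            yield ("gene", word, i)
        i = j


def parse_gpr(text: str) -> GprExpression:
    """Parse a GPR rule string into a :class:`GprExpression`.

    The empty (or all-whitespace) string parses to the always-true rule.
    ``and`` has precedence over ``or``; parentheses group explicitly.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        return GPR_TRUE
    expr, pos = _parse_or(tokens, 0, text)
    if pos != len(tokens):
        raise GprParseError("unexpected trailing token", tokens[pos][2])
    return expr


def _parse_or(tokens, pos, text):
    terms = []
    term, pos = _parse_and(tokens, pos, text)
    terms.append(term)
    while pos < len(tokens) and tokens[pos][:2] == ("op", "or"):
        term, pos = _parse_and(tokens, pos + 1, text)
        terms.append(term)
    if len(terms) == 1:
        return terms[0], pos
    return GprExpression(op="or", children=tuple(terms)), pos


def _parse_and(tokens, pos, text):
    factors = []
    factor, pos = _parse_atom(tokens, pos, text)
    factors.append(factor)
    while pos < len(tokens) and tokens[pos][:2] == ("op", "and"):
        factor, pos = _parse_atom(tokens, pos + 1, text)
        factors.append(factor)
    if len(factors) == 1:
        return factors[0], pos
    return GprExpression(op="and", children=tuple(factors)), pos


def _parse_atom(tokens, pos, text):
    if pos >= len(tokens):
        raise GprParseError("unexpected end of rule", len(text))
    kind, value, offset = tokens[pos]
    if kind == "gene":
        return GprExpression(op="gene", gene=value), pos + 1
    if (kind, value) == ("paren", "("):
        expr, pos = _parse_or(tokens, pos + 1, text)
        if pos >= len(tokens) or tokens[pos][:2] != ("paren", ")"):
            raise GprParseError("unbalanced parenthesis", offset)
        return expr, pos + 1
    raise GprParseError(f"unexpected token {value!r}", offset)
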