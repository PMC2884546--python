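"""Gene-protein-reaction (GPR) rules as boolean trees.

A GPR rule maps a set of gene deletions to reaction availability: the rule is
a boolean expression over gene identifiers combined with ``and`` / ``or``
(isozymes are ``or``-ed, subunits of a complex are ``and``-ed).  An empty rule
means the reaction is spontaneous or of unknown genetic basis and is never
disabled by gene deletions.

Trees are plain tuples: a leaf is a gene-id string, an internal node is
``("and", [children])`` or ``("or", [children])``, and the empty rule is
``None``.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Union

GPRTree = Union[None, str, tuple]

_TOKEN = re.compile(r"\(|\)|&&?|\|\|?|[^\s()&|]+")


class GPRParseError(ValueError):
    """Raised for malformed GPR expressions."""


def parse_gpr(text: Optional[str]) -> GPRTree:
    """Parse a GPR string such as ``"(b0001 and b0002) or b0003"``.

    ``and``/``or`` are case-insensitive; ``&``/``|`` are accepted as synonyms.
    ``and`` binds tighter than ``or``.  Empty or whitespace-only input yields
    ``None`` (the always-true rule).
    """
    if text is None or not text.strip():
        return None
    tokens = _TOKEN.findall(text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_op(tok: Optional[str], name: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        return low == name or (name == "and" and low in ("&", "&&")) or (
            name == "or" and low in ("|", "||")
        )

    def parse_or() -> GPRTree:
        terms = [parse_and()]
        while is_op(peek(), "or"):
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and() -> GPRTree:
        terms = [parse_atom()]
        while is_op(peek(), "and"):
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom() -> GPRTree:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR expression: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return take()

    tree = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR: {text!r}")
    return tree


def evaluate_gpr(tree: GPRTree, deleted_genes: Iterable[str]) -> bool:
    """Evaluate a GPR tree under a set of gene deletions.

    A leaf is true iff its gene is not deleted; the empty tree is true.
    """
    deleted = set(deleted_genes)

    def ev(node: GPRTree) -> bool:
        if node is None:
            return True
        if isinstance(node, str):
            return node not in deleted
        op, children = node
        if op == "and":
            return all(ev(c) for c in children)
        if op == "or":
            return any(ev(c) for c in children)
        raise GPRParseError(f"unknown GPR node {node!r}")

    return ev(tree)


def gpr_genes(tree: GPRTree) -> set:
    """All gene ids appearing in a GPR tree."""
    if tree is None:
        return set()
    if isinstance(tree, str):
        return {tree}
    out: set = set()
    for child in tree[1]:
        out |= gpr_genes(child)
    return out


def format_gpr(tree: GPRTree) -> str:
    """Canonical string form of a GPR tree (round-trips through parse_gpr)."""
    if tree is None:
        return ""
    if isinstance(tree, str):
        return tree
    op, children = tree
    sep = f" {op} "
    parts = []
    for child in children:
        text = format_gpr(child)
        if isinstance(child, tuple):
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)
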