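"""A small atom-selection mini-language.

Grammar (case-sensitive keywords, whitespace-tokenized)::

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := not_expr ("and" not_expr)*
    not_expr := "not" not_expr | atom_term | "(" expr ")"
    atom_term := "name" NAME | "resname" NAME | "chain" CHAR
               | "resid" A | "resid" A-B | "protein" | "nucleic" | "heavy"

"heavy" excludes hydrogens by element.  Resolution is deterministic for a
fixed topology and returns sorted unique 0-based atom indices; an empty
result is legal (e.g. contradictory conjunctions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import Topology

__all__ = ["Selection", "SelectionSyntaxError", "select"]


class SelectionSyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class Selection:
    expression: str
    resolved_indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.resolved_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.array(self.resolved_indices, dtype=int)


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError(
                f"unexpected end of expression at token {self.pos}"
            )
        self.pos += 1
        return tok

    def parse(self) -> set[int]:
        result = self.or_expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(
                f"unexpected token {self.peek()!r} at position {self.pos}"
            )
        return result

    def or_expr(self) -> set[int]:
        result = self.and_expr()
        while self.peek() == "or":
            self.take()
            result = result | self.and_expr()
        return result

    def and_expr(self) -> set[int]:
        result = self.not_expr()
        while self.peek() == "and":
            self.take()
            result = result & self.not_expr()
        return result

    def not_expr(self) -> set[int]:
        tok = self.peek()
        if tok == "not":
            self.take()
            universe = set(range(self.top.n_atoms))
            return universe - self.not_expr()
        if tok == "(":
            self.take()
            inner = self.or_expr()
            if self.take() != ")":
                raise SelectionSyntaxError(f"expected ')' at position {self.pos}")
            return inner
        return self.atom_term()

    def atom_term(self) -> set[int]:
        tok = self.take()
        atoms = self.top.atoms
        if tok == "name":
            value = self.take()
            return {i for i, a in enumerate(atoms) if a.name == value}
        if tok == "resname":
            value = self.take()
            return {i for i, a in enumerate(atoms) if a.residue_name == value}
        if tok == "chain":
            value = self.take()
            return {i for i, a in enumerate(atoms) if a.chain_id == value}
        if tok == "resid":
            value = self.take()
            if "-" in value[1:]:  # allow negative single resid, split on range dash
                lo_s, hi_s = value.rsplit("-", 1)
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError:
                    raise SelectionSyntaxError(
                        f"bad resid range {value!r} at position {self.pos}"
                    ) from None
            else:
                try:
                    lo = hi = int(value)
                except ValueError:
                    raise SelectionSyntaxError(
                        f"bad resid {value!r} at position {self.pos}"
                    ) from None
            return {i for i, a in enumerate(atoms) if lo <= a.residue_index <= hi}
        if tok == "protein":
            return {i for i, a in enumerate(atoms) if a.polymer_class == "protein"}
        if tok == "nucleic":
            return {i for i, a in enumerate(atoms) if a.polymer_class == "nucleic"}
        if tok == "heavy":
            return {i for i, a in enumerate(atoms) if a.element.upper() != "H"}
        raise SelectionSyntaxError(
            f"unknown keyword {tok!r} at position {self.pos - 1}"
        )


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


def select(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression against a topology."""
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionSyntaxError("empty selection expression")
    indices = _Parser(tokens, topology).parse()
    return Selection(expression=expression, resolved_indices=tuple(sorted(indices)))
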