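"""Minimal atom-selection language.

Grammar (EBNF)::

    expr     = or_expr ;
    or_expr  = and_expr , { "or" , and_expr } ;
    and_expr = not_expr , { "and" , not_expr } ;
    not_expr = "not" , not_expr | "(" , expr , ")" | primary ;
    primary  = "chain"   , ident
             | "resid"   , range { "," range }
             | "resname" , ident { "," ident }
             | "name"    , ident { "," ident }
             | "entity"  , ( "protein" | "ligand" | "water" )
             | "all" ;
    range    = int | int ":" int ;          (* inclusive *)

Examples: ``chain A and resid 10:20 and name CA``, ``entity ligand``,
``resname ORN or resname LEU``.  Matching is case-sensitive for chain ids and
case-insensitive for residue/atom names.
"""

from __future__ import annotations

import re

import numpy as np

from .errors import SelectionError

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {"chain", "resid", "resname", "name", "entity", "all", "and", "or", "not", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    tokens = _TOKEN_RE.findall(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], topology) -> None:
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def advance(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r} in selection")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.advance()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while self.peek() == "and":
            self.advance()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.advance()
            return ~self.not_expr()
        if tok == "(":
            self.advance()
            mask = self.or_expr()
            if self.advance() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        """Consume one or more comma-separated value tokens."""
        vals: list[str] = []
        while True:
            tok = self.peek()
            if tok is None or tok in _KEYWORDS:
                break
            self.advance()
            vals.extend(v for v in tok.split(",") if v)
            if not tok.endswith(","):
                nxt = self.peek()
                if nxt != ",":
                    break
                self.advance()
        if not vals:
            raise SelectionError("selection keyword is missing its value(s)")
        return vals

    def primary(self) -> np.ndarray:
        tok = self.advance()
        n = self.top.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "chain":
            vals = set(self._values())
            return np.isin(self.top.chain.astype(str), list(vals))
        if tok == "resid":
            mask = np.zeros(n, dtype=bool)
            for v in self._values():
                if ":" in v:
                    lo_s, hi_s = v.split(":")
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid range {v!r}") from exc
                    mask |= (self.top.resid >= lo) & (self.top.resid <= hi)
                else:
                    try:
                        mask |= self.top.resid == int(v)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid {v!r}") from exc
            return mask
        if tok == "resname":
            vals = {v.upper() for v in self._values()}
            return np.isin(np.char.upper(self.top.resname.astype(str)), list(vals))
        if tok == "name":
            vals = {v.upper() for v in self._values()}
            return np.isin(np.char.upper(self.top.atom_name.astype(str)), list(vals))
        if tok == "entity":
            vals = {v.lower() for v in self._values()}
            bad = vals - {"protein", "ligand", "water"}
            if bad:
                raise SelectionError(f"unknown entity class {sorted(bad)}")
            return np.isin(self.top.entity.astype(str), list(vals))
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select_atoms(topology, expression: str) -> np.ndarray:
    """Resolve *expression* against *topology*; returns sorted atom indices."""
    mask = _Parser(_tokenize(expression), topology).parse()
    return np.flatnonzero(mask)
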