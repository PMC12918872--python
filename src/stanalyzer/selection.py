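"""Minimal atom-selection language.

Grammar::

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := unary ("and" unary)*
    unary    := "not" unary | "(" expr ")" | term
    term     := "name" WORD | "resname" WORD | "resid" N[:M]
              | "segid" WORD | "element" WORD | "protein" | "water"

Selections resolve to a plain :class:`set` of 0-based atom indices against
an :class:`~stanalyzer.topology.AtomTable`.
"""

from __future__ import annotations

import re

import numpy as np

from .topology import AtomTable

__all__ = ["SelectionError", "parse_selection"]


class SelectionError(ValueError):
    """Raised on a grammar violation; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORD_TERMS = {"name", "resname", "resid", "segid", "element"}
_NULLARY_TERMS = {"protein", "water"}
_OPERATORS = {"and", "or", "not"}


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        tokens.append((m.group(0), m.start()))
    return tokens


class _Parser:
    def __init__(self, text: str, atoms: AtomTable):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0
        self.atoms = atoms

    def peek(self):
        if self.pos < len(self.tokens):
            return self.tokens[self.pos]
        return (None, len(self.text))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection", 0)
        mask = self.or_expr()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek()[0] == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek()[0] == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok, at = self.peek()
        if tok == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            tok2, at2 = self.next()
            if tok2 != ")":
                raise SelectionError("expected ')'", at2)
            return mask
        return self.term()

    def term(self) -> np.ndarray:
        tok, at = self.next()
        if tok is None:
            raise SelectionError("unexpected end of selection", at)
        low = tok.lower()
        a = self.atoms
        if low in _NULLARY_TERMS:
            return a.is_protein() if low == "protein" else a.is_water()
        if low in _KEYWORD_TERMS:
            arg, arg_at = self.next()
            if arg is None or arg in (")", "(") or arg.lower() in _OPERATORS:
                raise SelectionError(f"keyword {tok!r} needs an argument", arg_at)
            if low == "name":
                return np.char.strip(a.names) == arg
            if low == "resname":
                return np.char.strip(a.resnames) == arg
            if low == "segid":
                return np.char.strip(a.segids) == arg
            if low == "element":
                return a.elements == arg.upper()
            # resid N or N:M (inclusive range)
            m = re.fullmatch(r"(-?\d+)(?::(-?\d+))?", arg)
            if not m:
                raise SelectionError(f"bad resid argument {arg!r}", arg_at)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            return (a.resids >= lo) & (a.resids <= hi)
        if low in _OPERATORS or tok in ("(", ")"):
            raise SelectionError(f"unexpected token {tok!r}", at)
        raise SelectionError(f"unknown term {tok!r}", at)


def selection_mask(text: str, atoms: AtomTable) -> np.ndarray:
    """Boolean per-atom mask for a selection expression."""
    return _Parser(text, atoms).parse()


def parse_selection(text: str, atoms: AtomTable) -> set[int]:
    """Resolve a selection expression to a set of 0-based atom indices.

    An empty result is not an error; callers decide how to treat it.
    """
    mask = selection_mask(text, atoms)
    return set(int(i) for i in np.nonzero(mask)[0])


def selection_indices(text: str, atoms: AtomTable) -> np.ndarray:
    """Sorted index array form of :func:`parse_selection`."""
    return np.nonzero(selection_mask(text, atoms))[0]
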