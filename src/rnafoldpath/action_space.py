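"""Legality rules for base pairs and the shrinking action space.

The action space is the set of base pairs that may still be added to the
growing structure.  A pair is legal when its bases are Watson-Crick (A-U,
G-C) or wobble (G-U) complementary and the partners are at least three
bases apart along the sequence (j - i >= 4, i.e. >= 3 unpaired residues
between them — an off-by-one here changes every action space, so the rule
is stated explicitly).

Choosing a pair (i, j) removes every remaining pair that shares i or j and,
in pseudoknot-free mode, every pair crossing (i, j): what survives are pairs
entirely before i, entirely after j, enclosing (i, j), or enclosed by it.
In pseudoknot-allowed mode crossing pairs are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .structure import Pair, RnaSequence, pairs_cross

#: minimum sequence separation: j - i must be at least this
MIN_SEPARATION = 4

_CANONICAL = {frozenset("AU"), frozenset("CG"), frozenset("GU")}

PK_FREE = "pk_free"
PK_ALLOWED = "pk_allowed"


def can_pair(b1: str, b2: str) -> bool:
    """True iff {b1, b2} is A-U, G-C or the G-U wobble pair."""
    return frozenset((b1, b2)) in _CANONICAL


def is_legal(i: int, j: int, seq: RnaSequence) -> bool:
    """Sequence-level legality of pair (i, j): complementarity + separation."""
    if not 1 <= i < j <= len(seq):
        return False
    return j - i >= MIN_SEPARATION and can_pair(seq[i], seq[j])


@dataclass(frozen=True)
class ActionSpace:
    """The set of currently legal base pairs; shrinks monotonically."""

    legal: frozenset[Pair]
    mode: str = PK_FREE

    def __post_init__(self) -> None:
        if self.mode not in (PK_FREE, PK_ALLOWED):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "legal", frozenset(self.legal))

    def __len__(self) -> int:
        return len(self.legal)

    def __contains__(self, pair: Pair) -> bool:
        return tuple(pair) in self.legal

    def __iter__(self):
        return iter(sorted(self.legal))

    def sorted(self) -> list[Pair]:
        return sorted(self.legal)


def enumerate_initial(seq: RnaSequence, mode: str = PK_FREE) -> ActionSpace:
    """All legal pairs of the open strand (double loop over i < j)."""
    L = len(seq)
    legal = {
        (i, j)
        for i in range(1, L + 1)
        for j in range(i + MIN_SEPARATION, L + 1)
        if can_pair(seq[i], seq[j])
    }
    return ActionSpace(frozenset(legal), mode)


def restrict_after(space: ActionSpace, chosen: Pair) -> ActionSpace:
    """Action space remaining after selecting ``chosen``.

    Removes pairs sharing a position with ``chosen``; in pseudoknot-free
    mode also removes pairs crossing it.  The result is always a strict
    subset of the input (``chosen`` itself is removed).
    """
    chosen = (int(chosen[0]), int(chosen[1]))
    if chosen not in space:
        raise ValueError(f"pair {chosen} is not in the action space")
    i, j = chosen
    keep = set()
    for a, b in space.legal:
        if a in (i, j) or b in (i, j):
            continue
        if space.mode == PK_FREE and pairs_cross((i, j), (a, b)):
            continue
        keep.add((a, b))
    return ActionSpace(frozenset(keep), space.mode)
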