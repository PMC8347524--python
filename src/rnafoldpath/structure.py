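"""RNA sequences, secondary structures, and structure I/O.

A secondary structure is a set of base pairs ``(i, j)`` with 1-based,
inclusive coordinates and ``i < j``.  Pairs may carry a bracket-layer index:
layer 0 holds the nested (pseudoknot-free) part of the structure and is
written with round brackets; layers >= 1 hold pseudoknotted pairs and are
written with ``[]``, ``{}`` and ``<>``.

The distance between two structures is the cardinality of the symmetric
difference of their pair sets, which equals the sum of squared element
differences of the corresponding binary contact matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

ALPHABET = "AUCG"

#: bracket alphabets by layer; layer 0 is the nested layer
BRACKETS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]

Pair = tuple[int, int]


class StructureError(ValueError):
    """Raised for malformed structures or structure files."""


def normalize_sequence(text: str) -> str:
    """Uppercase, map T to U, and validate against the A/U/C/G alphabet."""
    seq = text.strip().upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in ALPHABET:
            raise StructureError(
                f"invalid residue {ch!r} at position {pos}; expected one of A/U/C/G"
            )
    return seq


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over A/U/C/G with 1-based indexing."""

    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_sequence(self.residues))
        if not self.residues:
            raise StructureError("empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} outside 1..{len(self.residues)}")
        return self.residues[i - 1]

    def __str__(self) -> str:
        return self.residues


def _check_pair(pair: Pair) -> Pair:
    i, j = pair
    if not (1 <= i < j):
        raise StructureError(f"invalid pair {pair}: need 1 <= i < j")
    return (int(i), int(j))


def pairs_cross(p: Pair, q: Pair) -> bool:
    """True iff the two pairs interleave (i < a < j < b or a < i < b < j)."""
    i, j = p
    a, b = q
    return (i < a < j < b) or (a < i < b < j)


@dataclass
class SecondaryStructure:
    """A set of base pairs with optional pseudoknot layer assignments.

    Parameters
    ----------
    pairs
        Iterable of 1-based ``(i, j)`` tuples with ``i < j``.
    layers
        Optional map pair -> bracket layer (0 = nested).  Pairs without an
        entry default to layer 0.
    length
        Optional sequence length the structure is defined over; required for
        matrix/dot-bracket output and distance checks.
    """

    pairs: frozenset[Pair]
    layers: dict[Pair, int] = field(default_factory=dict)
    length: int | None = None

    def __init__(
        self,
        pairs: Iterable[Pair] = (),
        layers: Mapping[Pair, int] | None = None,
        length: int | None = None,
    ) -> None:
        self.pairs = frozenset(_check_pair(p) for p in pairs)
        self.layers = {_check_pair(p): int(l) for p, l in (layers or {}).items()}
        self.length = length
        self._validate()

    def _validate(self) -> None:
        seen: dict[int, Pair] = {}
        for i, j in self.pairs:
            for pos in (i, j):
                if pos in seen:
                    raise StructureError(
                        f"position {pos} occurs in both {seen[pos]} and {(i, j)}"
                    )
                seen[pos] = (i, j)
            if self.length is not None and j > self.length:
                raise StructureError(f"pair {(i, j)} outside sequence of length {self.length}")
        nested = sorted(p for p in self.pairs if self.layers.get(p, 0) == 0)
        for a in range(len(nested)):
            for b in range(a + 1, len(nested)):
                if pairs_cross(nested[a], nested[b]):
                    raise StructureError(
                        f"layer-0 pairs {nested[a]} and {nested[b]} cross; "
                        "crossing pairs must be assigned a pseudoknot layer"
                    )

    def layer_of(self, pair: Pair) -> int:
        return self.layers.get(pair, 0)

    def nested_pairs(self) -> frozenset[Pair]:
        """Pairs in the pseudoknot-free layer (layer 0)."""
        return frozenset(p for p in self.pairs if self.layer_of(p) == 0)

    def pseudoknot_pairs(self) -> frozenset[Pair]:
        return frozenset(p for p in self.pairs if self.layer_of(p) > 0)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Pair) -> bool:
        return tuple(pair) in self.pairs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SecondaryStructure):
            return NotImplemented
        return self.pairs == other.pairs

    def __hash__(self) -> int:
        return hash(self.pairs)

    def add(self, pair: Pair) -> "SecondaryStructure":
        """Return a new structure with ``pair`` added.

        The pair is placed on the lowest layer where it crosses nothing,
        so crossing pairs (pseudoknot-allowed folding) land on layers >= 1.
        """
        pair = _check_pair(pair)
        by_layer: dict[int, list[Pair]] = {}
        for p in self.pairs:
            by_layer.setdefault(self.layer_of(p), []).append(p)
        layer = 0
        while any(pairs_cross(pair, q) for q in by_layer.get(layer, ())):
            layer += 1
        layers = dict(self.layers)
        layers[pair] = layer
        return SecondaryStructure(self.pairs | {pair}, layers, self.length)


def parse_dotbracket(text: str, length: int | None = None) -> SecondaryStructure:
    """Parse dot-bracket notation, one independent stack per bracket layer.

    Spaces are ignored (stray whitespace occurs in printed structures).
    Unbalanced brackets raise :class:`StructureError` naming the layer and
    1-based position.
    """
    text = text.strip().replace(" ", "")
    openers = {o: k for k, (o, _) in enumerate(BRACKETS)}
    closers = {c: k for k, (_, c) in enumerate(BRACKETS)}
    stacks: list[list[int]] = [[] for _ in BRACKETS]
    pairs: dict[Pair, int] = {}
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in openers:
            stacks[openers[ch]].append(pos)
        elif ch in closers:
            layer = closers[ch]
            if not stacks[layer]:
                raise StructureError(
                    f"unbalanced {ch!r} at position {pos} (layer {layer}): no matching opener"
                )
            i = stacks[layer].pop()
            pairs[(i, pos)] = layer
        else:
            raise StructureError(f"unexpected character {ch!r} at position {pos}")
    for layer, stack in enumerate(stacks):
        if stack:
            raise StructureError(
                f"unbalanced {BRACKETS[layer][0]!r} at position {stack[-1]} "
                f"(layer {layer}): never closed"
            )
    return SecondaryStructure(pairs.keys(), pairs, length or len(text))


def write_dotbracket(struct: SecondaryStructure, length: int | None = None) -> str:
    """Render a structure as dot-bracket text.

    Layer-0 pairs must be non-crossing (guaranteed by the structure
    invariant); pairs on layers beyond the available bracket alphabets raise.
    """
    L = length if length is not None else struct.length
    if L is None:
        raise StructureError("length required to write dot-bracket")
    chars = ["."] * L
    for i, j in sorted(struct.pairs):
        layer = struct.layer_of((i, j))
        if layer >= len(BRACKETS):
            raise StructureError(
                f"layer {layer} exceeds the {len(BRACKETS)} available bracket alphabets"
            )
        if j > L:
            raise StructureError(f"pair {(i, j)} outside length {L}")
        o, c = BRACKETS[layer]
        chars[i - 1] = o
        chars[j - 1] = c
    return "".join(chars)


def pairs_to_matrix(struct: SecondaryStructure, length: int | None = None) -> np.ndarray:
    """Strictly upper-triangular L x L binary contact matrix."""
    L = length if length is not None else struct.length
    if L is None:
        raise StructureError("length required for a contact matrix")
    mat = np.zeros((L, L), dtype=np.int8)
    for i, j in struct.pairs:
        if j > L:
            raise StructureError(f"pair {(i, j)} outside length {L}")
        mat[i - 1, j - 1] = 1
    return mat


def structure_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Symmetric-difference cardinality of the two pair sets.

    Identical to the sum of squared differences of the two upper-triangular
    contact matrices, since entries are 0/1.  Used as the episode reward
    (error from the native state): 0 means the structures are identical.
    """
    if a.length is not None and b.length is not None and a.length != b.length:
        raise StructureError(f"length mismatch: {a.length} vs {b.length}")
    return len(a.pairs ^ b.pairs)


# ---------------------------------------------------------------------------
# file I/O: dbn, bpseq, CT, FASTA


def read_structure_file(path: str | Path, fmt: str | None = None):
    """Read ``(RnaSequence, SecondaryStructure)`` from a dbn/bpseq/CT file.

    ``fmt`` may be ``"dbn"``, ``"bpseq"`` or ``"ct"``; if omitted it is taken
    from the file extension.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "dbn":
        return read_dbn(path)
    if fmt == "bpseq":
        return read_bpseq(path)
    if fmt == "ct":
        return read_ct(path)
    raise StructureError(f"unknown structure format {fmt!r}")


def read_dbn(path: str | Path):
    """dbn format: line 1 '>name' (optional), line 2 sequence, line 3 structure."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureError(f"{path}: expected sequence and structure lines")
    seq = RnaSequence(lines[0])
    struct = parse_dotbracket(lines[1], length=len(seq))
    if len(lines[1].replace(" ", "")) != len(seq):
        raise StructureError(
            f"{path}: structure length {len(lines[1])} != sequence length {len(seq)}"
        )
    return seq, struct


def write_dbn(path: str | Path, name: str, seq: RnaSequence, struct: SecondaryStructure) -> None:
    Path(path).write_text(f">{name}\n{seq}\n{write_dotbracket(struct, len(seq))}\n")


def _pairs_from_partner_rows(rows: list[tuple[int, str, int]], path) -> tuple[str, set[Pair]]:
    seq_chars: dict[int, str] = {}
    partner: dict[int, int] = {}
    for i, base, j in rows:
        seq_chars[i] = base
        partner[i] = j
    n = max(seq_chars)
    if sorted(seq_chars) != list(range(1, n + 1)):
        raise StructureError(f"{path}: positions are not contiguous 1..{n}")
    pairs: set[Pair] = set()
    for i, j in partner.items():
        if j == 0:
            continue
        if partner.get(j) != i:
            raise StructureError(
                f"{path}: inconsistent reciprocal pairing rows for ({i}, {j})"
            )
        pairs.add((min(i, j), max(i, j)))
    seq = "".join(seq_chars[i] for i in range(1, n + 1))
    return seq, pairs


def read_bpseq(path: str | Path):
    """bpseq format: one 'i base j' row per residue, j=0 for unpaired."""
    rows = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        fields = ln.split()
        if len(fields) != 3:
            raise StructureError(f"{path}: malformed bpseq row {ln!r}")
        rows.append((int(fields[0]), fields[1], int(fields[2])))
    seq, pairs = _pairs_from_partner_rows(rows, path)
    sequence = RnaSequence(seq)
    return sequence, _layered(pairs, len(sequence))


def write_bpseq(path: str | Path, seq: RnaSequence, struct: SecondaryStructure) -> None:
    partner = {i: 0 for i in range(1, len(seq) + 1)}
    for i, j in struct.pairs:
        partner[i], partner[j] = j, i
    Path(path).write_text(
        "".join(f"{i} {seq[i]} {partner[i]}\n" for i in range(1, len(seq) + 1))
    )


def read_ct(path: str | Path):
    """CT format: header line, then 6 columns (i base i-1 i+1 partner i)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    rows = []
    for ln in lines[1:]:
        fields = ln.split()
        if len(fields) < 6:
            raise StructureError(f"{path}: malformed CT row {ln!r}")
        rows.append((int(fields[0]), fields[1], int(fields[4])))
    seq, pairs = _pairs_from_partner_rows(rows, path)
    sequence = RnaSequence(seq)
    return sequence, _layered(pairs, len(sequence))


def write_ct(path: str | Path, name: str, seq: RnaSequence, struct: SecondaryStructure) -> None:
    partner = {i: 0 for i in range(1, len(seq) + 1)}
    for i, j in struct.pairs:
        partner[i], partner[j] = j, i
    L = len(seq)
    out = [f"{L} {name}"]
    for i in range(1, L + 1):
        out.append(f"{i} {seq[i]} {i - 1} {(i + 1) % (L + 1)} {partner[i]} {i}")
    Path(path).write_text("\n".join(out) + "\n")


def _layered(pairs: set[Pair], length: int) -> SecondaryStructure:
    """Assign pseudoknot layers greedily: each pair goes to the lowest layer
    where it crosses nothing already placed."""
    layers: dict[Pair, int] = {}
    placed: list[list[Pair]] = []
    for p in sorted(pairs):
        for k, layer_pairs in enumerate(placed):
            if not any(pairs_cross(p, q) for q in layer_pairs):
                layer_pairs.append(p)
                layers[p] = k
                break
        else:
            placed.append([p])
            layers[p] = len(placed) - 1
    return SecondaryStructure(pairs, layers, length)


def read_fasta(path: str | Path) -> list[tuple[str, RnaSequence]]:
    """Read (id, sequence) records from a FASTA file."""
    from Bio import SeqIO

    return [
        (rec.id, RnaSequence(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")
    ]
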