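"""Folding-path trees, modal paths, near-native filtering, pair-order maps.

Episodes record the ordered sequence of base pairs chosen from the open
strand to the final structure.  Ingesting many episodes into a trie keyed
by ordered pair-choice prefixes gives the folding-path tree; descending it
through the most-visited child at every level yields the modal path — the
most probable, interpreted as fastest, folding path.

For RNAs where almost no episode reaches the native state exactly (long
sequences, pseudoknotted natives folded in pseudoknot-free mode), paths
ending within one or two base pairs of the native structure — pseudoknot
pairs excluded from the comparison — are pooled instead, and their pair
formation orders are aggregated by mean rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import pandas as pd

from .structure import Pair, SecondaryStructure, write_dotbracket


@dataclass
class FoldingPath:
    """Ordered base-pair formation sequence with episode provenance."""

    pairs: list[Pair]
    episode_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [(int(i), int(j)) for i, j in self.pairs]
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("folding path repeats a base pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def final_structure(self, length: int | None = None) -> SecondaryStructure:
        s = SecondaryStructure((), length=length)
        for p in self.pairs:
            s = s.add(p)
        return s


class PathTreeNode:
    """Trie node: visits = episodes passing through this prefix."""

    __slots__ = ("pair", "visits", "terminal_count", "children")

    def __init__(self, pair: Pair | None = None):
        self.pair = pair
        self.visits = 0
        self.terminal_count = 0
        self.children: dict[Pair, PathTreeNode] = {}


def build_tree(paths: list[FoldingPath]) -> PathTreeNode:
    """Build the folding-path trie; root visits = number of episodes."""
    root = PathTreeNode()
    for path in paths:
        node = root
        node.visits += 1
        for pair in path.pairs:
            child = node.children.get(pair)
            if child is None:
                child = node.children[pair] = PathTreeNode(pair)
            child.visits += 1
            node = child
        node.terminal_count += 1
    return root


def modal_path(tree: PathTreeNode) -> FoldingPath:
    """Greedy max-visit descent from the root; ties break to the smallest
    (i, j); stops where more episodes end than continue down any child."""
    if tree.visits == 0:
        raise ValueError("empty path tree")
    pairs: list[Pair] = []
    node = tree
    while node.children:
        best_pair = min(
            node.children, key=lambda a: (-node.children[a].visits, a)
        )
        if node.terminal_count > node.children[best_pair].visits:
            break
        pairs.append(best_pair)
        node = node.children[best_pair]
    return FoldingPath(pairs)


def near_native_filter(
    paths: list[FoldingPath],
    native: SecondaryStructure,
    max_diff: int = 2,
    ignore_pseudoknots: bool = True,
) -> list[FoldingPath]:
    """Keep paths whose final structure is within ``max_diff`` base pairs of
    the native one; native pseudoknot-layer pairs are excluded from the
    comparison when ``ignore_pseudoknots`` (they are unreachable in
    pseudoknot-free folding)."""
    reference = native.nested_pairs() if ignore_pseudoknots else native.pairs
    kept = []
    for path in paths:
        final = set(path.pairs)
        if len(final ^ set(reference)) <= max_diff:
            kept.append(path)
    return kept


def pair_order_map(path: FoldingPath) -> dict[Pair, int]:
    """Formation rank of each pair: 1 = formed first."""
    return {pair: rank for rank, pair in enumerate(path.pairs, start=1)}


def aggregate_order_map(paths: list[FoldingPath]) -> dict[Pair, float]:
    """Mean formation rank over several (e.g. near-native) paths."""
    totals: dict[Pair, list[int]] = {}
    for path in paths:
        for pair, rank in pair_order_map(path).items():
            totals.setdefault(pair, []).append(rank)
    return {pair: sum(r) / len(r) for pair, r in sorted(totals.items())}


# ---------------------------------------------------------------------------
# exports


def paths_from_log(records: list[dict]) -> list[FoldingPath]:
    """Folding paths from parsed JSONL episode records."""
    return [
        FoldingPath([tuple(p) for p in rec["path"]], episode_ids=[k])
        for k, rec in enumerate(records)
    ]


def tree_to_json(tree: PathTreeNode) -> dict:
    """Nested-dict export of the path tree (plot-ready)."""
    return {
        "pair": list(tree.pair) if tree.pair else None,
        "visits": tree.visits,
        "terminal": tree.terminal_count,
        "children": [tree_to_json(c) for _, c in sorted(tree.children.items())],
    }


def write_order_map_tsv(order_map: dict[Pair, float], path: str | FsPath) -> None:
    """Write (i, j, rank) rows, ready for plotting."""
    df = pd.DataFrame(
        [(i, j, rank) for (i, j), rank in sorted(order_map.items())],
        columns=["i", "j", "rank"],
    )
    df.to_csv(path, sep="\t", index=False)


def modal_path_report(tree: PathTreeNode, length: int) -> dict:
    """Modal path as ordered pair list + dot-bracket of its final state."""
    path = modal_path(tree)
    final = path.final_structure(length)
    return {
        "path": [list(p) for p in path.pairs],
        "dotbracket": write_dotbracket(final, length),
        "n_pairs": len(path),
    }
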