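"""Monte Carlo tree search over base-pair selection states.

The search differs from classical UCT in three ways:

* nodes carry a value V (predicted error from the native structure, from
  the value head), a visit count N and a prior P (from the policy head);
  children are scored with ``-V + c * P * sqrt(N_parent) / (1 + N)`` — the
  minus sign because V is an error, lower is better;
* the random-rollout simulation step is replaced by a single value-network
  evaluation of the leaf state;
* when the episode advances from state S_t to S_{t+1}, the subtree rooted
  at the chosen child is kept (visit statistics and priors survive) and
  becomes the new search tree.

Classical UCT (``W/N + c * sqrt(ln T / N)``) is provided as a reference
scorer only.

Tie-breaking everywhere is "lexicographically smallest (i, j)", which makes
searches with a deterministic evaluator fully reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Protocol

logger = logging.getLogger(__name__)

import numpy as np

from .environment import FoldingState, apply_action, encode_state
from .network import PolicyValueNet, policy_prior
from .structure import Pair, SecondaryStructure, structure_distance

#: exploration constant of the pair-selection score (chosen large to
#: encourage exploration of the wide initial action space)
DEFAULT_EXPLORATION = 5.0
DEFAULT_SIMULATIONS = 2000


def score_node(V: float, N: int, P: float, N_parent: int, c: float) -> float:
    """Selection score of a child node: ``-V + c * P * sqrt(N_parent) / (1 + N)``.

    V is the node's (predicted) error from the native state, N its visit
    count, P its prior probability and N_parent the parent's visit count.
    """
    return -V + c * P * math.sqrt(N_parent) / (1.0 + N)


def uct_score(W: float, N: int, T: int, c: float = 2.0) -> float:
    """Classical UCT score ``W/N + c * sqrt(ln T / N)``; +inf when N = 0."""
    if N == 0:
        return math.inf
    return W / N + c * math.sqrt(math.log(T) / N)


class Evaluator(Protocol):
    """Maps a folding state to (per-action priors, value estimate)."""

    def __call__(self, state: FoldingState) -> tuple[dict[Pair, float], float]: ...


class NetworkEvaluator:
    """Priors and values from a policy/value network."""

    def __init__(self, net: PolicyValueNet, seq_channels: np.ndarray | None = None):
        self.net = net
        self.seq_channels = seq_channels

    def __call__(self, state: FoldingState) -> tuple[dict[Pair, float], float]:
        x = encode_state(state, self.seq_channels)
        policy, value = self.net.forward(x)
        if len(state.space) == 0:  # terminal state: value only, no priors
            return {}, value
        return policy_prior(policy, state.space, state.L), value


class OracleEvaluator:
    """Ground-truth evaluator: value = true current error from the native
    structure, priors uniform.  Used to test the search decoupled from
    learning."""

    def __init__(self, native: SecondaryStructure):
        self.native = native

    def __call__(self, state: FoldingState) -> tuple[dict[Pair, float], float]:
        actions = state.space.sorted()
        p = 1.0 / len(actions) if actions else 0.0
        priors = {a: p for a in actions}
        return priors, float(structure_distance(state.chosen, self.native))


@dataclass
class SearchConfig:
    n_simulations: int = DEFAULT_SIMULATIONS
    c: float = DEFAULT_EXPLORATION
    #: final-action choice: "visits" (robust, default) or "score"
    select_by: str = "visits"

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if self.c < 0:
            raise ValueError("exploration constant must be >= 0")
        if self.select_by not in ("visits", "score"):
            raise ValueError(f"unknown select_by {self.select_by!r}")


class SearchNode:
    """Tree node: prior P, visit count N, running value mean V."""

    __slots__ = ("action", "P", "N", "value_sum", "value_count", "children", "terminal")

    def __init__(self, action: Pair | None = None, P: float = 1.0):
        self.action = action
        self.P = P
        self.N = 0
        self.value_sum = 0.0
        self.value_count = 0
        self.children: dict[Pair, SearchNode] = {}
        self.terminal = False

    @property
    def V(self) -> float:
        """Running mean of the node's own evaluation and all backed-up leaf
        values; 0 before any evaluation."""
        if self.value_count == 0:
            return 0.0
        return self.value_sum / self.value_count

    @property
    def expanded(self) -> bool:
        return bool(self.children) or self.terminal


class SearchTree:
    """MCTS over folding states, with root reuse across episode steps."""

    def __init__(
        self,
        state: FoldingState,
        native: SecondaryStructure,
        evaluator: Evaluator,
        config: SearchConfig | None = None,
    ) -> None:
        self.root_state = state
        self.native = native
        self.evaluator = evaluator
        self.config = config or SearchConfig()
        self.root = SearchNode()

    # -- core steps ---------------------------------------------------------

    def _is_terminal_state(self, state: FoldingState) -> bool:
        if len(state.space) == 0:
            return True
        # native-match stop only when a native reference exists (prediction
        # mode searches against an empty reference)
        return len(self.native.pairs) > 0 and state.chosen.pairs == self.native.pairs

    def _expand(self, node: SearchNode, state: FoldingState) -> float:
        """Evaluate a leaf: either mark terminal (true final error) or attach
        children with priors.  Returns the value to back up."""
        if self._is_terminal_state(state):
            node.terminal = True
            return float(structure_distance(state.chosen, self.native))
        priors, value = self.evaluator(state)
        for action in state.space.sorted():
            node.children[action] = SearchNode(action, priors.get(action, 0.0))
        return float(value)

    def _select_child(self, node: SearchNode) -> "SearchNode":
        c = self.config.c
        best, best_score = None, -math.inf
        for action in sorted(node.children):
            child = node.children[action]
            # an unvisited child inherits the parent's value estimate: V is an
            # unbounded error, so a zero default would outrank every visited node
            V = child.V if child.value_count > 0 else node.V
            s = score_node(V, child.N, child.P, node.N, c)
            if s > best_score:
                best, best_score = child, s
        return best

    def run_simulation(self) -> None:
        """One selection descent, one expansion/evaluation, one backup."""
        if self.root.terminal or self._is_terminal_state(self.root_state):
            return
        if not self.root.expanded:
            # root evaluation; its own estimate seeds the value mean but
            # consumes no simulation visit
            value = self._expand(self.root, self.root_state)
            self.root.value_sum += value
            self.root.value_count += 1
        node, state = self.root, self.root_state
        path = [node]
        while node.expanded and not node.terminal:
            node = self._select_child(node)
            state = apply_action(state, node.action)
            path.append(node)
        if node.terminal:
            value = float(structure_distance(state.chosen, self.native))
        else:
            value = self._expand(node, state)
        for n in path:
            n.N += 1
            n.value_sum += value
            n.value_count += 1

    def search(self, n_simulations: int | None = None) -> dict[Pair, float]:
        """Run simulations and return the corrected policy: root-child visit
        counts normalized to a probability distribution."""
        if self._is_terminal_state(self.root_state):
            raise ValueError("cannot search from a terminal state")
        n = n_simulations if n_simulations is not None else self.config.n_simulations
        for _ in range(n):
            self.run_simulation()
        total = sum(ch.N for ch in self.root.children.values())
        if total == 0:
            k = len(self.root.children)
            return {a: 1.0 / k for a in self.root.children}
        return {a: ch.N / total for a, ch in sorted(self.root.children.items())}

    def best_action(self) -> Pair:
        """Final action: argmax visits (or score), smallest (i, j) on ties."""
        if not self.root.children:
            raise ValueError("root has no children; run search() first")
        if self.config.select_by == "visits":
            key: Callable[[Pair], float] = lambda a: self.root.children[a].N
        else:
            key = lambda a: score_node(
                self.root.children[a].V,
                self.root.children[a].N,
                self.root.children[a].P,
                self.root.N,
                self.config.c,
            )
        best = max(self.root.children, key=lambda a: (key(a), tuple(-x for x in a)))
        return best

    def advance_root(self, action: Pair) -> None:
        """Reuse the subtree under ``action`` as the new tree; statistics are
        preserved.  Advancing on a never-expanded action yields a fresh
        single-node tree."""
        action = (int(action[0]), int(action[1]))
        self.root_state = apply_action(self.root_state, action)
        child = self.root.children.get(action)
        if child is None:
            logger.debug("advance_root on unexpanded action %s: fresh tree", action)
            self.root = SearchNode()
        else:
            self.root = child
            self.root.action = None

    def trace(self) -> list[dict]:
        """Per-child search statistics of the current root (plot-ready)."""
        total = sum(ch.N for ch in self.root.children.values()) or 1
        return [
            {
                "action": list(a),
                "N": ch.N,
                "V": ch.V,
                "P": ch.P,
                "corrected": ch.N / total,
            }
            for a, ch in sorted(self.root.children.items())
        ]


def search(
    state: FoldingState,
    native: SecondaryStructure,
    evaluator: Evaluator,
    config: SearchConfig | None = None,
) -> dict[Pair, float]:
    """One-shot search from a state; returns the corrected policy."""
    return SearchTree(state, native, evaluator, config).search()
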