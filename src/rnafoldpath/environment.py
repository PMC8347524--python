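"""The RNAWorld2D folding environment.

An episode starts from the open strand (no pairs) and adds one base pair
per step.  The reward returned with every step is the current error from
the native structure: the symmetric-difference distance between the chosen
pair set and the native pair set.  Lower is better; the learner minimizes
the final reward.

The environment follows the conventional RL API: ``reset()`` returns the
initial state, ``step(action)`` returns ``(state, reward, done, info)``
packed in a :class:`StepResult`.  Termination is triggered by an empty
action space, by reaching the native structure exactly, or by a value
estimate below the stop threshold (the learned "stop signal").

State encoding for the network is an 18 x L x L tensor:

* channels 0-15 — one-hot ordered base-pair identity of each (i, j) cell,
  channel ``4 * index(base_i) + index(base_j)`` with base order A, U, C, G;
  fixed for the whole episode,
* channel 16 — mask of currently legal pairs (the action space),
* channel 17 — mask of pairs chosen so far (all zero at reset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .action_space import (
    PK_FREE,
    ActionSpace,
    enumerate_initial,
    is_legal,
    restrict_after,
)
from .structure import Pair, RnaSequence, SecondaryStructure, structure_distance

#: default stop threshold for the value-based termination signal
DEFAULT_STOP_THRESHOLD = 0.5

N_CHANNELS = 18
_BASE_INDEX = {"A": 0, "U": 1, "C": 2, "G": 3}


@dataclass
class FoldingState:
    """Immutable snapshot of an episode: sequence, chosen pairs, legal pairs."""

    seq: RnaSequence
    chosen: SecondaryStructure
    space: ActionSpace
    step_index: int = 0

    @property
    def L(self) -> int:
        return len(self.seq)


@dataclass
class StepResult:
    state: FoldingState
    reward: int
    done: bool
    info: dict[str, Any] = field(default_factory=dict)


def sequence_channels(seq: RnaSequence) -> np.ndarray:
    """The 16 x L x L ordered-pair sequence encoding (episode-constant)."""
    L = len(seq)
    idx = np.array([_BASE_INDEX[c] for c in str(seq)])
    chan = 4 * idx[:, None] + idx[None, :]
    out = np.zeros((16, L, L), dtype=np.float32)
    rows, cols = np.indices((L, L))
    out[chan, rows, cols] = 1.0
    return out


def encode_state(state: FoldingState, seq_channels: np.ndarray | None = None) -> np.ndarray:
    """Encode a folding state as the 18 x L x L network input."""
    L = state.L
    if seq_channels is None:
        seq_channels = sequence_channels(state.seq)
    out = np.zeros((N_CHANNELS, L, L), dtype=np.float32)
    out[:16] = seq_channels
    for i, j in state.space.legal:
        out[16, i - 1, j - 1] = 1.0
    for i, j in state.chosen.pairs:
        out[17, i - 1, j - 1] = 1.0
    return out


def is_terminal(
    state: FoldingState,
    native: SecondaryStructure,
    value_estimate: float | None = None,
    stop_threshold: float = DEFAULT_STOP_THRESHOLD,
) -> bool:
    """Terminal iff the space is empty, the native state is reached, or the
    value estimate (predicted remaining error) falls below the threshold.

    The native-match rule only applies to a non-empty native: prediction
    mode folds against an empty reference, which the open strand would
    otherwise match at reset."""
    if len(state.space) == 0:
        return True
    if len(native.pairs) > 0 and state.chosen.pairs == native.pairs:
        return True
    if value_estimate is not None and value_estimate < stop_threshold:
        return True
    return False


class RnaWorld2D:
    """Secondary-structure folding environment for a single RNA.

    Parameters
    ----------
    seq
        Target RNA sequence.
    native
        Native secondary structure (the target state).  Native pairs
        violating the pairing alphabet are kept — the native structure is
        ground truth and legality governs actions only — but a warning is
        emitted since such pairs are then unreachable.
    mode
        ``"pk_free"`` (crossing pairs pruned from the action space) or
        ``"pk_allowed"``.
    stop_threshold
        Value-estimate threshold for the learned stop signal.
    max_steps
        Hard cap on episode length (defaults to floor(L / 2), the maximum
        number of pairs a sequence can form).
    """

    name = "RNAWorld2D"

    def __init__(
        self,
        seq: RnaSequence,
        native: SecondaryStructure,
        mode: str = PK_FREE,
        stop_threshold: float = DEFAULT_STOP_THRESHOLD,
        max_steps: int | None = None,
    ) -> None:
        self.seq = seq
        self.native = native
        self.mode = mode
        self.stop_threshold = stop_threshold
        self.max_steps = max_steps if max_steps is not None else len(seq) // 2
        self.seq_channels = sequence_channels(seq)
        for i, j in native.pairs:
            if not is_legal(i, j, seq):
                warnings.warn(
                    f"native pair {(i, j)} violates the pairing rules and is "
                    "unreachable by any action",
                    stacklevel=2,
                )
        self.state: FoldingState | None = None

    def reset(self) -> FoldingState:
        """Initialize to the open strand with the full action space."""
        self.state = FoldingState(
            seq=self.seq,
            chosen=SecondaryStructure((), length=len(self.seq)),
            space=enumerate_initial(self.seq, self.mode),
            step_index=0,
        )
        return self.state

    def step(self, action: Pair, value_estimate: float | None = None) -> StepResult:
        """Add one base pair; returns the new state, reward, and done flag.

        ``value_estimate`` is the value head's prediction for the
        *post-action* state; if given and below the stop threshold the
        episode terminates (the learned stop signal).
        """
        if self.state is None:
            raise RuntimeError("call reset() before step()")
        action = (int(action[0]), int(action[1]))
        if action not in self.state.space:
            self._raise_illegal(action)
        new_state = apply_action(self.state, action)
        reward = structure_distance(new_state.chosen, self.native)
        done = (
            is_terminal(new_state, self.native, value_estimate, self.stop_threshold)
            or new_state.step_index >= self.max_steps
        )
        self.state = new_state
        return StepResult(new_state, reward, done, {"distance": reward})

    def _raise_illegal(self, action: Pair) -> None:
        i, j = action
        if not is_legal(i, j, self.seq):
            raise ValueError(
                f"action {action} violates sequence-level pairing rules "
                "(complementarity or minimum separation)"
            )
        raise ValueError(
            f"action {action} conflicts with already-chosen pairs "
            "(shared position or, in pseudoknot-free mode, crossing)"
        )

    def encode(self, state: FoldingState | None = None) -> np.ndarray:
        return encode_state(state or self.state, self.seq_channels)


def apply_action(state: FoldingState, action: Pair) -> FoldingState:
    """Pure transition: add ``action`` to the chosen set, shrink the space."""
    if action not in state.space:
        raise ValueError(f"action {action} not in the current action space")
    return FoldingState(
        seq=state.seq,
        chosen=state.chosen.add(action),
        space=restrict_after(state.space, action),
        step_index=state.step_index + 1,
    )
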