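"""Self-play training loop: episodes, replay buffer, curriculum sampling.

One episode folds a single RNA from the open strand: every step runs a
Monte Carlo tree search (budget ``n_simulations``), plays the most-visited
pair, and records ``(state, v_i, p_i)`` where ``p_i`` is the
search-corrected policy.  When the episode ends, the final error ``r``
(distance between the final and native structures) is attached to every
step, giving the ``(v_i, p_i, r)`` training triplets.  Triplets go into a
FIFO replay buffer (capacity 100,000); after each generation round a batch
(default 2024 samples) is drawn uniformly and used for one network update.
The value head is regressed on ``r``, the policy head on ``p_i``.

Multi-RNA curricula sample the next RNA with probability

    P_i = exp(V_i / (N_i * L_i)) / sum_k exp(V_k / (N_k * L_k))

where ``V_i`` is the cumulative error of RNA i so far (initialized to 1),
``N_i`` its sampling count (initialized to 1) and ``L_i`` its length —
RNAs that fold badly or have rarely been drawn get sampled more.

A generation round is ``workers`` episodes generated against a frozen
parameter snapshot, merged into the buffer before the update; rounds are
executed sequentially, so single-worker runs are bit-reproducible and
multi-worker runs are reproducible up to merge order.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .environment import RnaWorld2D, encode_state
from .mcts import Evaluator, NetworkEvaluator, SearchConfig, SearchTree
from .network import NetworkSpec, PolicyValueNet
from .structure import Pair, RnaSequence, SecondaryStructure, structure_distance

logger = logging.getLogger(__name__)

BUFFER_CAPACITY = 100_000
BATCH_SIZE = 2024


@dataclass
class TrainingConfig:
    """Run parameters; defaults are the reference settings of the method."""

    episodes: int = 1000
    n_simulations: int = 2000
    batch_size: int = BATCH_SIZE
    buffer_capacity: int = BUFFER_CAPACITY
    workers: int = 20
    seed: int = 0
    mode: str = "pk_free"
    stop_threshold: float = 0.5
    exploration_c: float = 5.0
    channels: tuple[int, int, int] = (32, 64, 128)
    lr: float = 0.001
    checkpoint_every: int = 50
    stochastic: bool = False

    def __post_init__(self) -> None:
        for name in ("episodes", "n_simulations", "batch_size", "buffer_capacity", "workers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class StepRecord:
    state: np.ndarray  # 18 x L x L input tensor before the action
    value: float  # v_i: value estimate of the state at search time
    policy: dict[Pair, float]  # p_i: search-corrected distribution
    action: Pair


@dataclass
class EpisodeRecord:
    rna_id: str
    L: int
    steps: list[StepRecord]
    reward: int  # final error r

    @property
    def path(self) -> list[Pair]:
        return [s.action for s in self.steps]


@dataclass
class TrainingSample:
    state: np.ndarray
    policy: np.ndarray  # dense L^2 target distribution
    value: float  # recorded v_i (diagnostic)
    reward: float  # r: the value-head training target


def run_episode(
    seq: RnaSequence,
    native: SecondaryStructure,
    evaluator: Evaluator,
    cfg: TrainingConfig,
    rng: np.random.Generator | None = None,
    rna_id: str = "rna",
) -> EpisodeRecord:
    """Fold one RNA with MCTS; returns the per-step records and final error.

    The search tree is reused across steps within the episode (the chosen
    child becomes the next root).  The stop signal is evaluated on the
    post-action state, so every episode takes at least one step.
    """
    env = RnaWorld2D(seq, native, cfg.mode, cfg.stop_threshold)
    state = env.reset()
    search_cfg = SearchConfig(n_simulations=cfg.n_simulations, c=cfg.exploration_c)
    tree = SearchTree(state, native, evaluator, search_cfg)
    steps: list[StepRecord] = []
    reward = structure_distance(state.chosen, native)
    while len(state.space) > 0 and not (
        len(native.pairs) > 0 and state.chosen.pairs == native.pairs
    ):
        policy = tree.search()
        if cfg.stochastic and rng is not None:
            actions = sorted(policy)
            probs = np.array([policy[a] for a in actions])
            action = actions[rng.choice(len(actions), p=probs / probs.sum())]
        else:
            action = tree.best_action()
        steps.append(
            StepRecord(
                state=env.encode(state),
                value=tree.root.V,
                policy=policy,
                action=action,
            )
        )
        tree.advance_root(action)
        # the stop signal is the value function's direct estimate of the
        # post-action state (the search mean anticipates future improvement
        # and would terminate episodes far from the native state)
        _, post_value = evaluator(tree.root_state)
        result = env.step(action, value_estimate=post_value)
        state = result.state
        reward = result.reward
        if result.done:
            break
    return EpisodeRecord(rna_id=rna_id, L=len(seq), steps=steps, reward=reward)


def finalize_samples(record: EpisodeRecord) -> list[TrainingSample]:
    """Attach the final episode reward r to every step sample."""
    samples = []
    for step in record.steps:
        L = record.L
        dense = np.zeros(L * L)
        for (i, j), p in step.policy.items():
            dense[(i - 1) * L + (j - 1)] = p
        samples.append(
            TrainingSample(
                state=step.state,
                policy=dense,
                value=step.value,
                reward=float(record.reward),
            )
        )
    return samples


class ReplayBuffer:
    """FIFO sample store: adding past capacity evicts the oldest samples."""

    def __init__(self, capacity: int = BUFFER_CAPACITY):
        self._q: deque[TrainingSample] = deque(maxlen=capacity)
        self.capacity = capacity

    def __len__(self) -> int:
        return len(self._q)

    def add(self, samples: Iterable[TrainingSample]) -> None:
        self._q.extend(samples)

    def sample(self, rng: np.random.Generator, k: int = BATCH_SIZE) -> list[TrainingSample]:
        """Uniform sample without replacement; clamped to the buffer size."""
        if len(self._q) == 0:
            raise ValueError("cannot sample from an empty replay buffer")
        if k >= len(self._q):
            if k > len(self._q):
                logger.debug("batch size %d > buffer size %d; returning all", k, len(self._q))
            return list(self._q)
        idx = rng.choice(len(self._q), size=k, replace=False)
        return [self._q[i] for i in idx]


@dataclass
class PoolEntry:
    rna_id: str
    seq: RnaSequence
    native: SecondaryStructure
    V: float = 1.0  # cumulative error sum, initialized to 1
    N: int = 1  # sampling count, initialized to 1

    @property
    def L(self) -> int:
        return len(self.seq)


class RnaPool:
    """Multi-RNA training pool with error/novelty-balanced sampling."""

    def __init__(self, entries: Sequence[PoolEntry]):
        if not entries:
            raise ValueError("empty RNA pool")
        self.entries = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def probabilities(self) -> np.ndarray:
        """P_i = softmax over exp(V_i / (N_i * L_i))."""
        z = np.array([e.V / (e.N * e.L) for e in self.entries])
        z = z - z.max()  # numerical stability; softmax is shift-invariant
        e = np.exp(z)
        return e / e.sum()

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(len(self.entries), p=self.probabilities()))

    def update(self, index: int, reward: float) -> None:
        """After an episode: V_i += r, N_i += 1."""
        self.entries[index].V += reward
        self.entries[index].N += 1


def sample_rna(pool: RnaPool, rng: np.random.Generator) -> int:
    """Draw the next training RNA index according to the pool distribution."""
    return pool.sample(rng)


def compute_advantage(Q: float, V: float) -> float:
    """Advantage A = Q - V (diagnostic: how much better an action is than
    the state's baseline value)."""
    return Q - V


def _train_batch(net: PolicyValueNet, batch: list[TrainingSample]) -> tuple[float, float, float]:
    """One Adam update; mixed sequence lengths are grouped into per-L passes."""
    by_L: dict[int, list[TrainingSample]] = {}
    for s in batch:
        by_L.setdefault(s.state.shape[-1], []).append(s)
    vl = pl = tot = 0.0
    for group in by_L.values():
        x = np.stack([s.state for s in group])
        tp = np.stack([s.policy for s in group])
        tv = np.array([s.reward for s in group])
        v, p, t = net.train_step(x, tp, tv)
        w = len(group) / len(batch)
        vl, pl, tot = vl + w * v, pl + w * p, tot + w * t
    return vl, pl, tot


@dataclass
class TrainingResult:
    net: PolicyValueNet
    episodes: list[EpisodeRecord]
    rewards: list[int]
    losses: list[tuple[float, float, float]]
    config: TrainingConfig


def train(
    pool: RnaPool,
    cfg: TrainingConfig,
    out_dir: str | Path | None = None,
    evaluator_factory=None,
) -> TrainingResult:
    """Alternate self-play generation rounds with network updates.

    Each round generates ``cfg.workers`` episodes against the current
    (frozen) parameters, merges their samples into the replay buffer,
    updates per-RNA curriculum statistics, then performs one sampled-batch
    network update.  Fully seeded from ``cfg.seed``.

    ``evaluator_factory``, if given, maps the current network to the
    evaluator used for search (tests substitute a ground-truth oracle
    here); the default is the network itself.
    """
    rng = np.random.default_rng(cfg.seed)
    net = PolicyValueNet(
        NetworkSpec(channels=cfg.channels, lr=cfg.lr), seed=int(cfg.seed) % (2**31)
    )
    buffer = ReplayBuffer(cfg.buffer_capacity)
    episodes: list[EpisodeRecord] = []
    losses: list[tuple[float, float, float]] = []
    out_path = Path(out_dir) if out_dir is not None else None
    log_fh = None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "config.json").write_text(
            json.dumps({**cfg.__dict__, "channels": list(cfg.channels)}, indent=2)
        )
        log_fh = open(out_path / "episodes.jsonl", "w")
    try:
        while len(episodes) < cfg.episodes:
            n_round = min(cfg.workers, cfg.episodes - len(episodes))
            round_records = []
            for _ in range(n_round):
                idx = pool.sample(rng)
                entry = pool.entries[idx]
                evaluator = (
                    evaluator_factory(net) if evaluator_factory is not None else NetworkEvaluator(net)
                )
                record = run_episode(
                    entry.seq, entry.native, evaluator, cfg, rng, rna_id=entry.rna_id
                )
                round_records.append((idx, record))
            for idx, record in round_records:
                pool.update(idx, record.reward)
                buffer.add(finalize_samples(record))
                episodes.append(record)
                if log_fh is not None:
                    log_fh.write(json.dumps(episode_to_json(record)) + "\n")
            if len(buffer) > 0:
                batch = buffer.sample(rng, cfg.batch_size)
                losses.append(_train_batch(net, batch))
            if (
                out_path is not None
                and cfg.checkpoint_every > 0
                and (len(episodes) // cfg.workers) % cfg.checkpoint_every == 0
            ):
                net.save(out_path / "checkpoint.npz")
        if out_path is not None:
            net.save(out_path / "checkpoint.npz")
    finally:
        if log_fh is not None:
            log_fh.close()
    return TrainingResult(
        net=net,
        episodes=episodes,
        rewards=[rec.reward for rec in episodes],
        losses=losses,
        config=cfg,
    )


def episode_to_json(record: EpisodeRecord) -> dict:
    """JSONL episode log entry: id, path, final error, sparse per-step policies."""
    return {
        "rna_id": record.rna_id,
        "L": record.L,
        "path": [list(a) for a in record.path],
        "r": record.reward,
        "policies": [
            {f"{i},{j}": round(p, 6) for (i, j), p in step.policy.items() if p > 0}
            for step in record.steps
        ],
    }


def read_episode_log(path: str | Path) -> list[dict]:
    """Parse a JSONL episode log back into dictionaries with tuple paths."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        rec["path"] = [tuple(a) for a in rec["path"]]
        records.append(rec)
    return records
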