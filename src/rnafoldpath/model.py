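"""High-level Model/Results interface for single-RNA folding-path learning.

``FoldingPathModel`` binds one RNA (sequence + native secondary structure)
to a training configuration; ``fit()`` runs the self-play loop and returns
a ``FoldingPathResults`` holding the trained network, the per-episode
errors, the folding-path tree and the modal ("fastest") folding path, with
a ``summary()`` table in the spirit of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import path_analysis as pa
from .fixtures import get_fixture
from .mcts import NetworkEvaluator
from .structure import (
    RnaSequence,
    SecondaryStructure,
    parse_dotbracket,
    read_structure_file,
    structure_distance,
    write_dotbracket,
)
from .trainer import (
    PoolEntry,
    RnaPool,
    TrainingConfig,
    TrainingResult,
    run_episode,
    train,
)


class FoldingPathModel:
    """Folding-path learner for a single RNA.

    Parameters
    ----------
    seq, native
        The RNA and its native secondary structure (the target state).
    config
        Training configuration; defaults to the reference settings
        (1000 episodes, 2000 searches per step).
    rna_id
        Label used in logs and summaries.
    """

    def __init__(
        self,
        seq: RnaSequence,
        native: SecondaryStructure,
        config: TrainingConfig | None = None,
        rna_id: str = "rna",
    ) -> None:
        self.seq = seq
        self.native = native
        self.config = config or TrainingConfig()
        self.rna_id = rna_id

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_strings(
        cls,
        sequence: str,
        dotbracket: str,
        config: TrainingConfig | None = None,
        rna_id: str = "rna",
    ) -> "FoldingPathModel":
        seq = RnaSequence(sequence)
        return cls(seq, parse_dotbracket(dotbracket, length=len(seq)), config, rna_id)

    @classmethod
    def from_file(
        cls, path: str | Path, config: TrainingConfig | None = None
    ) -> "FoldingPathModel":
        seq, native = read_structure_file(path)
        return cls(seq, native, config, rna_id=Path(path).stem)

    @classmethod
    def from_fixture(
        cls, fixture_id: str, config: TrainingConfig | None = None
    ) -> "FoldingPathModel":
        f = get_fixture(fixture_id)
        return cls(f.sequence, f.native, config, rna_id=f.id)

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        seed: int | None = None,
        out_dir: str | Path | None = None,
        evaluator_factory=None,
    ) -> "FoldingPathResults":
        """Run the self-play training loop and analyse the episode paths."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        pool = RnaPool([PoolEntry(self.rna_id, self.seq, self.native)])
        result = train(pool, cfg, out_dir=out_dir, evaluator_factory=evaluator_factory)
        return FoldingPathResults(self, result)


class FoldingPathResults:
    """Estimates and diagnostics from a fitted folding-path model."""

    def __init__(self, model: FoldingPathModel, training: TrainingResult):
        self.model = model
        self.training = training
        self.rewards = np.array(training.rewards)
        paths = [
            pa.FoldingPath(rec.path, episode_ids=[k])
            for k, rec in enumerate(training.episodes)
        ]
        self.paths = paths
        self.tree = pa.build_tree(paths)
        self.modal_path = pa.modal_path(self.tree)
        self.modal_structure = self.modal_path.final_structure(len(model.seq))

    @property
    def net(self):
        return self.training.net

    @property
    def modal_distance(self) -> int:
        """Error of the modal path's final state from the native structure."""
        return structure_distance(self.modal_structure, self.model.native)

    def near_native_paths(self, max_diff: int = 2) -> list[pa.FoldingPath]:
        return pa.near_native_filter(self.paths, self.model.native, max_diff)

    def order_map(self, max_diff: int = 2) -> dict:
        """Mean pair-formation ranks over near-native paths."""
        return pa.aggregate_order_map(self.near_native_paths(max_diff))

    def predict_path(self) -> pa.FoldingPath:
        """Deterministic greedy refold with the trained network."""
        cfg = replace(self.model.config, stochastic=False)
        record = run_episode(
            self.model.seq,
            self.model.native,
            NetworkEvaluator(self.net),
            cfg,
            rna_id=self.model.rna_id,
        )
        return pa.FoldingPath(record.path)

    def episode_frame(self) -> pd.DataFrame:
        """Per-episode diagnostics: final error and path length."""
        return pd.DataFrame(
            {
                "episode": np.arange(len(self.rewards)),
                "reward": self.rewards,
                "path_length": [len(rec.path) for rec in self.training.episodes],
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        n = len(self.rewards)
        head = self.rewards[: max(1, n // 3)]
        tail = self.rewards[-max(1, n // 3):]
        lines = [
            "Folding-path learning results",
            "=" * 46,
            f"RNA id:              {self.model.rna_id}",
            f"Sequence length:     {len(self.model.seq)}",
            f"Native pairs:        {len(self.model.native)}",
            f"Episodes:            {n}",
            f"Searches per step:   {self.model.config.n_simulations}",
            f"Median error, first third:  {np.median(head):.1f}",
            f"Median error, last third:   {np.median(tail):.1f}",
            f"Episodes at native (r=0):   {int((self.rewards == 0).sum())}",
            "-" * 46,
            "Modal (fastest) folding path:",
            "  " + " -> ".join(f"({i},{j})" for i, j in self.modal_path),
            f"  final state: {write_dotbracket(self.modal_structure, len(self.model.seq))}",
            f"  error from native: {self.modal_distance}",
        ]
        return "\n".join(lines)
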