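"""Episodes, replay buffer, curriculum sampling, training loop."""

import json

import numpy as np
import pytest

from rnafoldpath.fixtures import gen_hairpin
from rnafoldpath.mcts import OracleEvaluator
from rnafoldpath.structure import RnaSequence, SecondaryStructure
from rnafoldpath.trainer import (
    PoolEntry,
    ReplayBuffer,
    RnaPool,
    TrainingConfig,
    compute_advantage,
    episode_to_json,
    finalize_samples,
    read_episode_log,
    run_episode,
    sample_rna,
    train,
)

TINY = dict(workers=1, channels=(4, 8, 8), batch_size=64)


class TestRunEpisode:
    def test_single_pair_fold(self, tiny_hairpin):
        seq, native = tiny_hairpin
        cfg = TrainingConfig(episodes=1, n_simulations=8, **TINY)
        rec = run_episode(seq, native, OracleEvaluator(native), cfg)
        assert rec.path == [(1, 5)] and rec.reward == 0

    def test_oracle_guided_hairpin_reaches_native(self, hairpin44):
        seq, native = hairpin44
        cfg = TrainingConfig(episodes=1, n_simulations=64, **TINY)
        rec = run_episode(seq, native, OracleEvaluator(native), cfg)
        assert rec.reward == 0
        assert set(rec.path) == set(native.pairs)

    def test_empty_native_reference_still_folds(self, tiny_hairpin):
        """Prediction-style episodes (no native pairs) do not stop at reset."""
        seq, _ = tiny_hairpin
        empty = SecondaryStructure((), length=len(seq))
        cfg = TrainingConfig(episodes=1, n_simulations=8, **TINY)
        rec = run_episode(seq, empty, OracleEvaluator(empty), cfg)
        assert rec.path == [(1, 5)]

    def test_episode_length_bounded(self, hairpin44):
        seq, native = hairpin44
        cfg = TrainingConfig(episodes=1, n_simulations=16, **TINY)
        rec = run_episode(seq, native, OracleEvaluator(native), cfg)
        assert len(rec.steps) <= len(seq) // 2


class TestFinalizeSamples:
    def test_reward_attached_to_every_step(self, hairpin44):
        seq, native = hairpin44
        cfg = TrainingConfig(episodes=1, n_simulations=32, **TINY)
        rec = run_episode(seq, native, OracleEvaluator(native), cfg)
        samples = finalize_samples(rec)
        assert len(samples) == len(rec.steps)
        assert all(s.reward == rec.reward for s in samples)
        for s in samples:
            assert s.policy.sum() == pytest.approx(1.0)
            assert s.state.shape == (18, 12, 12)


class TestReplayBuffer:
    def test_fifo_eviction_at_capacity(self):
        buf = ReplayBuffer(capacity=100_000)
        buf.add(range(100_001))
        assert len(buf) == 100_000
        assert buf._q[0] == 1  # sample 0 (the first inserted) was evicted
        assert buf._q[-1] == 100_000

    def test_sampling_clamped_to_size(self):
        buf = ReplayBuffer(capacity=100)
        buf.add(range(10))
        assert len(buf.sample(np.random.default_rng(0), 2024)) == 10

    def test_sampling_deterministic_under_fixed_seed(self):
        buf = ReplayBuffer(capacity=100)
        buf.add(range(50))
        b1 = buf.sample(np.random.default_rng(4), 20)
        b2 = buf.sample(np.random.default_rng(4), 20)
        assert b1 == b2

    def test_sampling_empty_buffer_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ReplayBuffer().sample(np.random.default_rng(0), 5)


class TestCurriculumSampling:
    def test_identical_entries_sample_uniformly(self):
        seq, native = gen_hairpin(1, 3)
        pool = RnaPool([PoolEntry("a", seq, native), PoolEntry("b", seq, native)])
        assert np.allclose(pool.probabilities(), [0.5, 0.5])

    def test_hand_evaluated_probability(self):
        # V=(1,1), N=(1,2), L=(10,10): P_1 = e^0.1 / (e^0.1 + e^0.05)
        seq, _ = gen_hairpin(3, 4)  # L = 10
        native = SecondaryStructure((), length=10)
        pool = RnaPool(
            [
                PoolEntry("a", seq, native, V=1.0, N=1),
                PoolEntry("b", seq, native, V=1.0, N=2),
            ]
        )
        expected = np.exp(0.1) / (np.exp(0.1) + np.exp(0.05))
        assert pool.probabilities()[0] == pytest.approx(expected, abs=1e-6)
        assert pool.probabilities()[0] == pytest.approx(0.5125, abs=1e-3)

    def test_probability_increases_with_cumulative_error(self):
        seq, native = gen_hairpin(1, 3)
        p_prev = 0.0
        for v in (1.0, 2.0, 5.0, 20.0):
            pool = RnaPool(
                [
                    PoolEntry("a", seq, native, V=v, N=1),
                    PoolEntry("b", seq, native, V=1.0, N=1),
                ]
            )
            p = pool.probabilities()[0]
            assert p > p_prev
            p_prev = p

    def test_probabilities_sum_to_one_on_random_pools(self):
        rng = np.random.default_rng(8)
        seq, native = gen_hairpin(1, 3)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            pool = RnaPool(
                [
                    PoolEntry(
                        f"r{k}", seq, native,
                        V=float(rng.uniform(0.1, 200)),
                        N=int(rng.integers(1, 50)),
                    )
                    for k in range(n)
                ]
            )
            assert pool.probabilities().sum() == pytest.approx(1.0)
            idx = sample_rna(pool, rng)
            assert 0 <= idx < n

    def test_update_accumulates_error_and_count(self):
        seq, native = gen_hairpin(1, 3)
        pool = RnaPool([PoolEntry("a", seq, native)])
        pool.update(0, 4.0)
        assert pool.entries[0].V == 5.0 and pool.entries[0].N == 2


class TestAdvantage:
    @pytest.mark.parametrize("Q,V,expected", [(1.0, 1.0, 0.0), (3.0, 1.0, 2.0), (1.0, 3.0, -2.0)])
    def test_advantage_is_q_minus_v(self, Q, V, expected):
        assert compute_advantage(Q, V) == expected


class TestTrain:
    def test_writes_episode_log(self, tmp_path, tiny_hairpin):
        seq, native = tiny_hairpin
        cfg = TrainingConfig(episodes=2, n_simulations=8, seed=5, **TINY)
        pool = RnaPool([PoolEntry("hp", seq, native)])
        result = train(pool, cfg, out_dir=tmp_path)
        assert len(result.episodes) == 2
        log = read_episode_log(tmp_path / "episodes.jsonl")
        assert len(log) == 2
        assert all(rec["rna_id"] == "hp" for rec in log)
        assert (tmp_path / "checkpoint.npz").exists()
        assert (tmp_path / "config.json").exists()

    def test_single_worker_runs_are_bit_reproducible(self):
        seq, native = gen_hairpin(2, 3)
        cfg = TrainingConfig(episodes=4, n_simulations=12, seed=3, **TINY)
        runs = []
        for _ in range(2):
            pool = RnaPool([PoolEntry("hp", seq, native)])
            result = train(pool, cfg)
            runs.append(
                [json.dumps(episode_to_json(rec)) for rec in result.episodes]
            )
        assert runs[0] == runs[1]

    def test_oracle_value_function_folds_every_episode(self, hairpin44):
        seq, native = hairpin44
        cfg = TrainingConfig(episodes=5, n_simulations=64, seed=1, **TINY)
        pool = RnaPool([PoolEntry("hp", seq, native)])
        result = train(
            pool, cfg, evaluator_factory=lambda net: OracleEvaluator(native)
        )
        assert result.rewards == [0, 0, 0, 0, 0]

    def test_generation_round_merges_before_update(self, tiny_hairpin):
        seq, native = tiny_hairpin
        cfg = TrainingConfig(
            episodes=4, n_simulations=8, seed=2, workers=2,
            channels=(4, 8, 8), batch_size=64,
        )
        pool = RnaPool([PoolEntry("hp", seq, native)])
        result = train(pool, cfg)
        # 4 episodes in rounds of 2 -> 2 network updates
        assert len(result.losses) == 2
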