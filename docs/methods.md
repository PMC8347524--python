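# Methods

This note documents the model, the numerical and design choices, what the
synthetic data does and does not emulate, and known limitations.

## State space and environment

A folding state is a set of base pairs over a fixed RNA sequence, with
1-based coordinates and i < j everywhere (internal code may use 0-based
offsets but never serializes them). Pair legality is sequence-only:
unordered {bᵢ, bⱼ} must be A-U, G-C or G-U, and j − i ≥ 4, i.e. at least
three unpaired residues between partners. The separation rule is the single
most consequential constant in the package — an off-by-one changes every
action space — so it is defined once (`action_space.MIN_SEPARATION = 4`)
and cross-checked against a brute-force enumeration in the tests.

Two modes govern how the action space shrinks after a pair (i, j) is
chosen. Both remove every pair sharing i or j. Pseudoknot-free mode also
removes every crossing pair (i < a < j < b or a < i < b < j), leaving the
four compatible regions: both-before, both-after, enclosing, enclosed.
Pseudoknot-allowed mode retains crossing pairs; chosen crossing pairs are
assigned to pseudoknot layers ≥ 1 (greedily, lowest non-crossing layer).
The native structure is never consulted when building action spaces.

The reward is the symmetric-difference count between the chosen and native
pair sets. Because contact matrices are strictly upper-triangular and
binary, this equals the sum of squared matrix differences, and the native
structure of an RNA with k pairs sits at distance k from the open strand.
Reward is an error: positive, and minimized.

Episodes terminate when (a) the action space empties, (b) the chosen set
equals the native set (a training convenience — the state cannot improve
further), or (c) the value head's estimate of the **post-action** state
falls below a stop threshold τ = 0.5. Evaluating the post-action state
means every episode performs at least one step; a pre-action stop at reset
would produce zero-step episodes with no training samples and could
deadlock learning before the value head has seen any data. The stop signal
uses the value function's direct estimate, not the search tree's running
mean: the tree mean anticipates achievable *future* error and would halt
episodes far from the native state.

## Input encoding

The network input is an 18×L×L tensor. Channels 0–15 one-hot the ordered
base identity of each (i, j) cell — channel 4·index(bᵢ) + index(bⱼ), base
order A, U, C, G, row = 5′ partner — and are constant through an episode.
Channel 16 marks the current action space, channel 17 the chosen pairs.
Ordered (16-channel) rather than unordered encoding is a free choice; the
channel count is fixed, the ordering convention is ours.

## Network

Three shared 3×3 convolutions (channels 32/64/128 by default, ReLU, "same"
padding so L survives the trunk), then:

* value head: 1×1 conv to 4 channels, ReLU, global average pooling, dense
  to a scalar, softplus — the output is a predicted error and must be > 0;
* policy head: 1×1 conv to 2 channels, ReLU, 1×1 conv to 1 channel,
  flatten to L² logits, softmax.

Both heads are fully convolutional/pooled, so a single parameter set serves
any sequence length; batches of mixed lengths are split into per-length
forward passes. Losses are mean squared error (value) and cross-entropy
against the search-corrected distribution (policy), summed; the optimizer
is Adam with learning rate 0.001. Forward, backward and Adam are written
explicitly on numpy arrays (im2col-style convolutions); gradients are
verified against central finite differences in the tests, away from ReLU
kinks where finite differences are invalid.

Raw policies are masked to the action space and renormalized; if every
legal entry underflows to zero the distribution falls back to uniform over
legal actions. Masking an empty space is an error — callers must already
have stopped.

## Search

Nodes carry a prior P (policy head, masked and normalized over siblings), a
visit count N, and a value V maintained as the running mean of the node's
own first evaluation and every value backed up through it. Selection
descends by the score −V + c·P·√N′/(1+N) with c = 5; ties break to the
lexicographically smallest (i, j), making searches with a deterministic
evaluator fully reproducible. Classical UCT (W/N + c·√(ln T/N)) is provided
as a reference scorer only and is not used by the system.

Choices the formulation leaves open, resolved as follows:

* **Unvisited children** inherit the parent's V for scoring. V is an
  unbounded error, so a zero default would outrank every honestly-valued
  visited node and force pure breadth-first scans of wide action spaces.
* **Terminal in-tree states** (empty space, or native reached) back up
  their true final error rather than a value-head estimate. The trainer
  knows the reward function, exactly as a game-playing learner knows game
  outcomes; measurements during development showed the value-net-everywhere
  alternative gives self-play no outcome grounding at small simulation
  budgets and diverges (policy and value reinforce each other's errors).
* **Root evaluation** at first expansion seeds the root's value mean but
  consumes no simulation, so k simulations always distribute exactly k
  visits over the root's children (visit conservation, tested).
* **Final action** = argmax visit count (argmax score available behind
  `SearchConfig.select_by="score"`); trees key on ordered prefixes; the
  subtree under the played action is reused at the next step, and each step
  runs a fresh full simulation budget on top of the reused statistics.
* Prediction mode is deterministic end-to-end; setting
  `TrainingConfig.stochastic` samples actions from the corrected policy
  instead, yielding alternative plausible pathways.

## Training loop

An episode's per-step records (state tensor, corrected value vᵢ, corrected
policy pᵢ, action) receive the final error r when the episode ends; the
value-head target is r (the recorded vᵢ is diagnostic only). Samples live
in a FIFO buffer of capacity 100,000; batches of 2024 (the printed figure,
possibly a typo for 2048 — configurable) are drawn uniformly without
replacement, clamped to the buffer size. The advantage A = Q − V is
implemented as a diagnostic; the optimization itself is supervised on the
search-corrected targets.

A generation round produces `workers` episodes against frozen parameters,
merges their samples, then performs one network update. Rounds execute
sequentially: with a numpy network there is nothing to gain from threads,
and the contract the concurrency is meant to satisfy — order-independent
merge, bit-reproducible single-worker runs — holds regardless. Multi-worker
runs are reproducible up to merge order.

Multi-RNA curricula draw RNA i with probability
Pᵢ = exp(Vᵢ/(Nᵢ·Lᵢ)) / Σₖ exp(Vₖ/(Nₖ·Lₖ)), where Vᵢ is the cumulative
episode error (initialized to 1) and Nᵢ the sampling count. Nᵢ is
initialized to 1 so the initial exponent is 1/Lᵢ; the formulation gives the
initial Vᵢ but not the initial Nᵢ. Per-RNA search trees are discarded
between episodes; only within-episode root reuse is kept.

## Curated fixtures and synthetic data

Six published RNAs ship as fixtures, each storing the printed strings
verbatim plus a curated, machine-checked version; tests run against the
curated data and the notes record every correction:

* `PDB_00972`: the printed sequence is 31 nt against a stated length of 30
  and is inconsistent with its own pair list ((1,17) would be C-U); one G
  removed from the GGG run restores a sequence under which all six printed
  pairs are legal. The printed dot-bracket is unbalanced; the explicit pair
  list is authoritative.
* `1Y26`: printed sequence 73 characters vs stated length 71; the
  71-character dot-bracket is balanced (22 nested + 3 pseudoknot pairs) and
  is the curated structure source; the sequence is truncated and flagged.
* `bpRNA_RFAM_25409`: printed dot-bracket has one surplus ')'; the
  corrected 38-character structure's seven stem pairs are all legal under
  the printed sequence.

`gen_hairpin(stem, loop)` produces Watson-Crick stems around an all-A loop
(all-G stem without an rng — e.g. GGGGAAAACCCC — random stems with one).
It emulates the cleanest possible folding task: a unique nested native
reachable from every prefix. It does not emulate competing near-native
attractors, multi-domain structures, pseudoknotted natives, or sequence
lengths where the action space dwarfs the simulation budget — so passing
hairpin tests demonstrates the machinery (search, learning loop, path
statistics), not performance on hard RNAs.

## Scaled-down problem sizes

The reference configuration (1000 episodes × 2000 simulations per step,
20-worker rounds) is the package default; the test suite and the
acceptance script exercise the full loop at sizes chosen to keep a complete
run in minutes on one CPU: the 12-nt hairpin, 150 episodes, 64 simulations
per step, a (8, 16, 32)-channel network, batch 256, single worker. At this
scale the search with true terminal backups already solves the toy at
episode 1 under some seeds, so learning-curve improvement is seed-dependent:
the interesting observable is the stop-signal oscillation (blocks of
truncated episodes while the value head calibrates around τ) and the modal
path, which ends at the native state across the seeds we ran. Oracle-valued
reachability uses 64–200 simulations per step on the 30-nt fixtures.

## Known limitations

* The value/policy loop without terminal grounding (pure paper reading)
  diverges at desk scale; with grounding, toy tasks saturate quickly. The
  regime in between — where learning visibly bends the error curve — needs
  larger RNAs and budgets than a test suite should spend.
* Learned paths rank pair choices, not free energies; no thermodynamic
  claim is made or checkable here.
* Pseudoknot-allowed mode retains crossing pairs in the action space but
  native pseudoknots still count as errors in pseudoknot-free training
  (the near-native filter exists precisely for this case).
* The networkx-based structure drawing of the original system is out of
  scope; path trees, order maps and episode logs export as JSON/TSV for
  external plotting.
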