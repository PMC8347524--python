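import numpy as np
import pytest

from rnafoldpath.action_space import enumerate_initial, restrict_after
from rnafoldpath.fixtures import gen_hairpin
from rnafoldpath.structure import RnaSequence, SecondaryStructure


@pytest.fixture
def hairpin44():
    """12-nt GGGGAAAACCCC hairpin: 4 stem pairs, 4-nt loop."""
    return gen_hairpin(4, 4)


@pytest.fixture
def tiny_hairpin():
    """5-nt GAAAC: a single legal pair (1, 5)."""
    return gen_hairpin(1, 3)


def random_sequence(rng: np.random.Generator, max_len: int = 40, min_len: int = 5) -> RnaSequence:
    L = int(rng.integers(min_len, max_len + 1))
    return RnaSequence("".join(rng.choice(list("AUCG")) for _ in range(L)))


def random_structure(
    rng: np.random.Generator, seq: RnaSequence, mode: str = "pk_free"
) -> SecondaryStructure:
    """Random valid structure built by a random legal folding trajectory."""
    space = enumerate_initial(seq, mode)
    struct = SecondaryStructure((), length=len(seq))
    while len(space) > 0 and rng.random() > 0.15:
        actions = space.sorted()
        action = actions[int(rng.integers(len(actions)))]
        struct = struct.add(action)
        space = restrict_after(space, action)
    return struct
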