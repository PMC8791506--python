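import numpy as np
import pytest

from ptmnet.partitions import Partition, RandomSource, build_universe


@pytest.fixture
def rng():
    return RandomSource(12345)


def random_partition_blocks(labels, rand):
    """Cheap (non-uniform) random partition for property tests: assign each
    label to one of a random number of urns, drop empty urns."""
    k = rand.integers(1, len(labels) + 1)
    assign = rand.integers(0, k, size=len(labels))
    blocks = {}
    for lab, g in zip(labels, assign):
        blocks.setdefault(int(g), []).append(lab)
    return list(blocks.values())


@pytest.fixture
def make_random_partition():
    def make(n_reactions, seed):
        uni = build_universe(n_reactions)
        rand = np.random.default_rng(seed)
        return Partition(uni, random_partition_blocks(list(uni.labels), rand))

    return make
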