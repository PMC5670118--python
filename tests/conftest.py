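import numpy as np
import pytest

from texsig import shmax, stimuli


@pytest.fixture(scope="session")
def small_corpus():
    """5 families x 4 pairs of 64-px structured/scrambled stimuli."""
    return stimuli.build_corpus(5, 4, size=64, seed=11)


@pytest.fixture(scope="session")
def desk_model(small_corpus):
    """One trained desk-scale SHMAX (shared across tests; training images
    are drawn from the same families but disjoint from the corpus)."""
    train = stimuli.build_corpus(5, 6, size=64, seed=23, family_seed=11)
    spec = shmax.desk_spec(n_big=3, m=(24, 32, 48), kernels=(7, 5, 3),
                           strides=(2, 1, 1))
    model = shmax.ShmaxModel(spec, n_patches_per_image=100, n_iters=10)
    return model.fit([p.cm.pixels for p in train.pairs], seed=7)
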