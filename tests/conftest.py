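import numpy as np
import pytest

from mixtox import featurize as fz
from mixtox import synthetic as syn


def _chemical_classification_data(effect_size: float, seed: int):
    """Single-chemical toxic/non-toxic benchmark: descriptors carry the class
    signal (shifted means), SMILES strings are random (no signal)."""
    cfg = syn.SyntheticConfig(
        n_toxic=200, n_nontoxic=200, n_desc=10,
        effect_size=effect_size, seed=seed,
    )
    sp = syn.generate_pool(cfg)
    smiles = [r.smiles for r in sp.pool.records]
    vocab = fz.build_vocabulary(smiles)
    tensor = fz.one_hot_encode(smiles, vocab)
    X = sp.descriptors.to_numpy()
    y = np.array([sp.pool.labels[i] for i in sp.pool.ids])
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(y.size)
    train, test = perm[:300], perm[300:]
    return tensor, X, y, train, test


def subset_tensor(tensor: fz.OneHotTensor, idx) -> fz.OneHotTensor:
    return fz.OneHotTensor(
        data=tensor.data[idx], lengths=tensor.lengths[idx], vocab=tensor.vocab
    )


@pytest.fixture(scope="session")
def separable_benchmark():
    """400 chemicals with a 3-pooled-SD descriptor class shift."""
    return _chemical_classification_data(effect_size=3.0, seed=11)


@pytest.fixture(scope="session")
def null_benchmark():
    """400 chemicals with zero class separation (no-information control)."""
    return _chemical_classification_data(effect_size=0.0, seed=23)


@pytest.fixture(scope="session")
def small_pool():
    return syn.generate_pool(
        syn.SyntheticConfig(n_toxic=60, n_nontoxic=60, n_desc=8, seed=5)
    )
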