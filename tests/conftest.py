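import numpy as np
import pytest

from vflda import ANIMAL_SUBCATEGORIES, Lexicon


@pytest.fixture(scope="session")
def animals_lexicon() -> Lexicon:
    return Lexicon(frozenset(
        w for words in ANIMAL_SUBCATEGORIES.values() for w in words))


@pytest.fixture(scope="session")
def make_profile():
    """Build a K-vector topic profile from {topic: probability} with the
    remaining mass spread negligibly over the other topics."""

    def _make(spikes: dict[int, float], K: int = 14) -> np.ndarray:
        p = np.full(K, 1e-6)
        for k, v in spikes.items():
            p[k] = v
        return p / p.sum()

    return _make


@pytest.fixture(scope="session")
def onehot_profiles():
    """word -> one-hot profile over the planted subcategories, for tests that
    bypass LDA fitting and use the planted structure directly."""
    names = list(ANIMAL_SUBCATEGORIES)
    K = len(names)
    profiles: dict[str, np.ndarray] = {}
    from vflda import OUT_OF_CATEGORY

    for k, name in enumerate(names):
        vec = np.zeros(K)
        vec[k] = 1.0
        for w in ANIMAL_SUBCATEGORIES[name]:
            profiles[w] = vec
        for w in OUT_OF_CATEGORY[name]:
            profiles[w] = vec
    return profiles
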