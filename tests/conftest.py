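import numpy as np
import pytest

from harsample.datasets import FeatureDataset


class ScriptedRng:
    """Stand-in generator replaying a fixed script of draws.

    ``integers(n)`` pops from ``ints`` (values asserted < n); ``random()``
    pops from ``uniforms``; ``choice`` pops from ``ints`` (ignoring weights).
    Lets tests pin down exactly which seed/neighbor/u a sampler uses.
    """

    def __init__(self, ints=(), uniforms=()):
        self._ints = list(ints)
        self._uniforms = list(uniforms)

    def integers(self, n):
        v = self._ints.pop(0)
        assert v < n, f"scripted draw {v} out of range {n}"
        return v

    def random(self):
        return self._uniforms.pop(0)

    def choice(self, n, size=None, replace=True, p=None):
        if size is None:
            return self.integers(n)
        return np.array([self.integers(n) for _ in range(size)])


@pytest.fixture
def scripted_rng():
    return ScriptedRng


def blob_dataset(counts, seed=0, d=2, spread=1.0, centers=None, names=None):
    """Gaussian blob FeatureDataset with exact class counts."""
    rng = np.random.default_rng(seed)
    names = names or [chr(ord("A") + i) for i in range(len(counts))]
    blocks, labels = [], []
    for c, n in enumerate(counts):
        if centers is not None:
            mean = np.asarray(centers[c], dtype=float)
        else:
            mean = np.zeros(d)
            mean[c % d] = 6.0 * c
        blocks.append(rng.normal(mean, spread, size=(n, d)))
        labels += [names[c]] * n
    return FeatureDataset.from_labels(np.vstack(blocks), labels, class_names=names)


@pytest.fixture
def make_blobs():
    return blob_dataset


@pytest.fixture
def imbalanced_ds():
    """Two well-separated classes, counts 20 and 5."""
    return blob_dataset([20, 5], seed=0)
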