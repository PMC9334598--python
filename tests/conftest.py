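import numpy as np
import pytest

from speciesdelim.priors import CollapseConfig, sample_tree_from_collapse_prior


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_tree():
    """Factory: random collapse-prior trees for property checks."""

    def make(n=6, epsilon=0.1, omega=0.4, lam=2.0, seed=0):
        r = np.random.default_rng(seed)
        return sample_tree_from_collapse_prior(
            n, CollapseConfig(epsilon, omega), lam, r
        )

    return make


class FakeRng:
    """Scripted random source for deterministic proposal-kernel checks."""

    def __init__(self, integers=(), randoms=(), normals=()):
        self._integers = list(integers)
        self._randoms = list(randoms)
        self._normals = list(normals)

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)

    def random(self, *args, **kwargs):
        return self._randoms.pop(0)

    def standard_normal(self, *args, **kwargs):
        return self._normals.pop(0)


@pytest.fixture
def fake_rng():
    return FakeRng
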