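import numpy as np
import pytest

from ordqual.profiles import ProviderSet, QualityScale


@pytest.fixture
def two_practice_set() -> ProviderSet:
    """The two-practice example: A = 40/10/50, B = 30/30/40, equal weights."""
    scale = QualityScale("ordinal", ("poor", "OK", "good"))
    mass = np.array([[0.40, 0.10, 0.50], [0.30, 0.30, 0.40]])
    return ProviderSet(scale, ["A", "B"], mass, np.array([0.5, 0.5]), ["all", "all"])


def random_provider_set(rng, K=8, Q=5, n_groups=3) -> ProviderSet:
    """Random valid provider set for property tests."""
    scale = QualityScale("ordinal", tuple(f"c{q}" for q in range(Q)))
    mass = rng.dirichlet(np.ones(Q), size=K)
    weights = rng.uniform(0.2, 2.0, size=K)
    groups = [f"g{i % n_groups}" for i in range(K)]
    return ProviderSet(scale, [f"p{i}" for i in range(K)], mass, weights, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
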