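import numpy as np
import pytest

import hicscape as h


def random_network(n: int, seed: int, density: float = 1.0) -> h.ContactNetwork:
    """Random symmetric nonnegative contact matrix with zero diagonal."""
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.uniform(0.5, 5.0, size=(n, n)), k=1)
    if density < 1.0:
        upper *= np.triu(rng.random((n, n)) < density, k=1)
    w = upper + upper.T
    return h.ContactNetwork(
        chromosome="test",
        resolution=100_000,
        n_bins_total=n,
        retained_bins=np.arange(n),
        weights=w,
    )


def random_partition(n: int, k: int, seed: int) -> h.Partition:
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, k, size=n)
    labels[:k] = np.arange(k)  # every community nonempty
    return h.canonicalize(h.Partition(labels=labels))


@pytest.fixture
def tiny_net() -> h.ContactNetwork:
    return random_network(10, seed=7)


@pytest.fixture(scope="session")
def planted_instance():
    """Small planted-block map shared by optimizer/ensemble tests."""
    spec = h.SyntheticSpec(
        n_bins=120, block_sizes=(20,) * 6, alpha_true=0.75, mu=20.0,
        epsilon=5.0, seed=11,
    )
    net, planted = h.generate_contacts(spec)
    return spec, net, planted
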